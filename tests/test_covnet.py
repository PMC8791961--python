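"""Structural covariance networks: residualisation, Fisher-z edge tests,
density thresholding, graph metrics against brute-force enumeration,
hubs, Louvain communities against exhaustive search, and the permutation
and bootstrap inference."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cortmorph import covnet, synthio
from cortmorph.covnet import CovarianceMatrix, ThresholdedGraph
from cortmorph.types import GROUP_VH, MorphometricTable, ValidationError

from conftest import two_group_meta


def _table(values, meta):
    values = np.asarray(values, float)
    return MorphometricTable(
        pd.DataFrame(
            values,
            index=pd.Index(meta["subject_id"], name="subject_id"),
            columns=[f"r{j}" for j in range(values.shape[1])],
        )
    )


def _cov(r, n=100, label="VH", labels=None):
    r = np.asarray(r, float)
    if labels is None:
        labels = [f"r{i}" for i in range(r.shape[0])]
    return CovarianceMatrix(
        label, pd.DataFrame(r, index=labels, columns=labels), n
    )


def _graph(adj, labels=None):
    adj = np.asarray(adj, bool)
    if labels is None:
        labels = [f"n{i}" for i in range(adj.shape[0])]
    return ThresholdedGraph(0.1, adj, int(adj.sum() // 2), "VH", list(labels))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_metrics(adj):
    """Path-enumeration graph metrics for small graphs."""
    n = adj.shape[0]
    # all shortest path counts by enumerating simple paths
    def all_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in range(n):
                if adj[v, w] and w not in path:
                    stack.append((w, path + [w]))
        return paths

    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    betw = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t:
                continue
            paths = all_paths(s, t)
            if not paths:
                continue
            d = min(len(p) for p in paths) - 1
            dist[s, t] = dist[t, s] = d
            shortest = [p for p in paths if len(p) - 1 == d]
            for p in shortest:
                for v in p[1:-1]:
                    betw[v] += 1.0 / len(shortest)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    nodal_eff = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    glob_eff = inv.sum() / (n * (n - 1)) if n > 1 else 0.0
    local_eff = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        local_eff[v] = brute_force_metrics(sub)["global_efficiency"]
    return {
        "degree": adj.sum(axis=1),
        "betweenness": betw,
        "nodal_efficiency": nodal_eff,
        "local_efficiency": local_eff,
        "global_efficiency": glob_eff,
    }


def partitions_rgs(n):
    """All set partitions of range(n) as restricted growth strings."""
    a = [0] * n
    while True:
        yield list(a)
        b = [0] * n
        for k in range(1, n):
            b[k] = max(b[k - 1], a[k - 1])
        j = n - 1
        while j > 0 and a[j] == b[j] + 1:
            j -= 1
        if j == 0:
            return
        a[j] += 1
        for k in range(j + 1, n):
            a[k] = 0


def exhaustive_best_modularity(G):
    nodes = list(G.nodes)
    n = len(nodes)
    m = G.number_of_edges()
    if m == 0:
        return 0.0
    idx = {v: i for i, v in enumerate(nodes)}
    deg = np.array([G.degree(v) for v in nodes], float)
    edges = [(idx[u], idx[v]) for u, v in G.edges]
    best = -1.0
    for a in partitions_rgs(n):
        lab = np.asarray(a)
        q = sum(1 for u, v in edges if lab[u] == lab[v]) / m
        for c in range(lab.max() + 1):
            dc = deg[lab == c].sum()
            q -= (dc / (2 * m)) ** 2
        best = max(best, q)
    return best


# ---------------------------------------------------------------------------
# residualisation and covariance
# ---------------------------------------------------------------------------

class TestResidualize:
    def test_orthogonal_covariates_leave_correlations(self):
        meta = two_group_meta(40, seed=0)
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((80, 5))
        t = _table(vals, meta)
        meta2 = meta.copy()
        meta2["age"] = 1.0  # constant-ish covariate via intercept only
        resid = covnet.residualize(t, meta, covariates=(), homogeneity_check=False)
        raw_corr = np.corrcoef(vals, rowvar=False)
        res_corr = np.corrcoef(resid.to_numpy(), rowvar=False)
        assert np.allclose(raw_corr, res_corr, atol=1e-10)

    def test_residuals_orthogonal_to_covariate(self):
        meta = two_group_meta(50, seed=2)
        rng = np.random.default_rng(3)
        vals = 2.0 * meta["age"].to_numpy()[:, None] + rng.standard_normal((100, 3))
        resid = covnet.residualize(_table(vals, meta), meta, ("age",),
                                   homogeneity_check=False)
        R = resid.to_numpy()
        age = meta["age"].to_numpy()
        for j in range(3):
            assert abs(np.corrcoef(R[:, j], age)[0, 1]) < 1e-10
        assert np.allclose(R.mean(axis=0), 0.0, atol=1e-10)


class TestCovarianceMatrix:
    def test_coupled_regions_r_one(self):
        meta = two_group_meta(20, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        vals = np.column_stack([x, x, rng.standard_normal(40)])
        resid = _table(vals, meta)
        cov = covnet.covariance_matrix(resid, meta, GROUP_VH)
        assert cov.r.iloc[0, 1] == pytest.approx(1.0)
        arr = cov.values()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)

    def test_factor_model_frobenius_convergence(self, atlas68):
        truth = synthio.default_truth(
            atlas68, sites=("siteA",), site_shift_sd=0.0, site_scale_sd=1e-9,
            seed=4,
        )
        table, meta = synthio.generate_cohort(atlas68, truth, 400, seed=5)
        resid = covnet.residualize(table, meta, ("age", "gender"),
                                   homogeneity_check=False)
        cov = covnet.covariance_matrix(resid, meta, GROUP_VH)
        target = truth.implied_correlation(GROUP_VH)
        assert np.linalg.norm(cov.values() - target) < 0.1 * 68

    def test_small_group_rejected(self):
        meta = two_group_meta(5, seed=0)
        with pytest.raises(ValidationError):
            covnet.covariance_matrix(
                _table(np.random.default_rng(0).standard_normal((10, 3)), meta),
                meta, GROUP_VH,
            )


class TestCompareEdges:
    def test_equal_correlations_z_zero(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        e = covnet.compare_edges(_cov(r, 100, "VH"), _cov(r, 100, "noVH"))
        assert e["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert e["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_fisher_z(self):
        r1 = np.array([[1.0, 0.8], [0.8, 1.0]])
        r2 = np.array([[1.0, 0.2], [0.2, 1.0]])
        e = covnet.compare_edges(_cov(r1, 103, "VH"), _cov(r2, 103, "noVH"))
        expected = (np.arctanh(0.8) - np.arctanh(0.2)) / np.sqrt(2.0 / 100.0)
        assert e["z"].iloc[0] == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(6.33, abs=0.01)
        assert e["p"].iloc[0] < 1e-9

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((50, 4))
        B = rng.standard_normal((60, 4))
        ca = _cov(np.corrcoef(A.T), 50, "VH")
        cb = _cov(np.corrcoef(B.T), 60, "noVH")
        e1 = covnet.compare_edges(ca, cb)
        e2 = covnet.compare_edges(cb, ca)
        assert np.allclose(e1["z"], -e2["z"])
        assert np.allclose(e1["p"], e2["p"])
        assert np.allclose(e1["delta_r2"], -e2["delta_r2"])

    def test_perfect_correlation_clamped(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="clamped"):
            e = covnet.compare_edges(_cov(r, 50, "VH"),
                                     _cov(np.eye(2), 50, "noVH"))
        assert np.isfinite(e["z"]).all()


class TestThresholdGraph:
    def test_study_density_edge_count(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((300, 68))
        cov = _cov(np.corrcoef(Y.T), 300)
        g = covnet.threshold_graph(cov, 0.13)
        assert g.k == 296  # round(0.13 * 68*67/2) = round(296.14)

    def test_single_edge_is_global_max(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((50, 10))
        r = np.corrcoef(Y.T)
        cov = _cov(r, 50)
        with pytest.warns(UserWarning, match="sweep"):
            g = covnet.threshold_graph(cov, 1.0 / 45.0)
        iu = np.triu_indices(10, 1)
        i, j = np.unravel_index(
            np.argmax(np.where(np.tri(10, k=-1).T.astype(bool), r, -np.inf)),
            (10, 10),
        )
        assert g.adjacency[i, j]
        assert g.k == 1

    def test_monotone_nesting(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((100, 30))
        cov = _cov(np.corrcoef(Y.T), 100)
        g_lo = covnet.threshold_graph(cov, 0.05)
        g_hi = covnet.threshold_graph(cov, 0.20)
        assert not np.any(g_lo.adjacency & ~g_hi.adjacency)

    def test_negative_correlations_never_included(self):
        r = -0.5 * np.ones((6, 6)) + 1.5 * np.eye(6)
        r[0, 1] = r[1, 0] = 0.4
        cov = _cov(r, 50)
        with pytest.warns(UserWarning):
            g = covnet.threshold_graph(cov, 0.5)
        assert g.k == 1
        assert g.adjacency[0, 1]

    def test_realised_density_within_one_edge(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((200, 40))
        cov = _cov(np.corrcoef(Y.T), 200)
        P = 40 * 39 / 2
        for d in covnet.DENSITY_SWEEP:
            g = covnet.threshold_graph(cov, d)
            assert abs(g.k - d * P) <= 1.0


class TestNodeMetrics:
    def test_path_graph_hand_values(self):
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        nm = covnet.node_metrics(_graph(adj, ["a", "b", "c"]))
        assert nm.per_node.loc["b", "betweenness"] == pytest.approx(1.0)
        assert nm.per_node.loc["a", "betweenness"] == 0.0
        assert nm.per_node.loc["b", "nodal_efficiency"] == pytest.approx(1.0)
        assert nm.global_efficiency == pytest.approx((1 + 1 + 0.5) / 3)

    def test_complete_graph_efficiencies_one(self):
        adj = ~np.eye(4, dtype=bool)
        nm = covnet.node_metrics(_graph(adj))
        assert np.allclose(nm.per_node["nodal_efficiency"], 1.0)
        assert np.allclose(nm.per_node["local_efficiency"], 1.0)
        assert nm.global_efficiency == pytest.approx(1.0)

    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(3, 8))
            adj = rng.random((n, n)) < 0.45
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            nm = covnet.node_metrics(_graph(adj))
            ref = brute_force_metrics(adj)
            assert np.array_equal(nm.per_node["degree"].to_numpy(), ref["degree"])
            assert np.allclose(
                nm.per_node["betweenness"], ref["betweenness"], atol=1e-9
            )
            assert np.allclose(
                nm.per_node["nodal_efficiency"], ref["nodal_efficiency"], atol=1e-9
            )
            assert np.allclose(
                nm.per_node["local_efficiency"], ref["local_efficiency"], atol=1e-9
            )
            assert nm.global_efficiency == pytest.approx(
                ref["global_efficiency"], abs=1e-9
            )


class TestHubs:
    def _metrics_from_betweenness(self, rows):
        out = {}
        for d, b in rows.items():
            per_node = pd.DataFrame(
                {
                    "degree": 0, "betweenness": b,
                    "nodal_efficiency": 0.0, "local_efficiency": 0.0,
                },
                index=[f"n{i}" for i in range(len(b))],
            )
            out[d] = covnet.NodeMetrics(per_node, 0.0, d, "VH")
        return out

    def test_threshold_is_eight_of_sixteen(self):
        """Qualification at exactly 8 of the study's 16 densities makes a
        hub; 7 of 16 does not."""
        densities = covnet.DENSITY_SWEEP
        assert len(densities) == 16
        base = [0.0, 0.0, 0.0, 10.0]
        rows8 = {
            d: ([20.0, 0, 0, 0] if i < 8 else [0.0, 20, 0, 0])
            for i, d in enumerate(densities)
        }
        hubs = covnet.identify_hubs(self._metrics_from_betweenness(rows8))
        assert hubs.threshold == 8
        assert "n0" in hubs.hubs
        rows7 = {
            d: ([20.0, 0, 0, 0] if i < 7 else [0.0, 20, 0, 0])
            for i, d in enumerate(densities)
        }
        hubs = covnet.identify_hubs(self._metrics_from_betweenness(rows7))
        assert "n0" not in hubs.hubs

    def test_star_centre_always_qualifies(self):
        adj = np.zeros((6, 6), bool)
        adj[0, 1:] = adj[1:, 0] = True
        metrics = {
            d: covnet.node_metrics(_graph(adj)) for d in (0.05, 0.10, 0.15)
        }
        hubs = covnet.identify_hubs(metrics)
        assert "n0" in hubs.hubs

    def test_zero_variance_density_qualifies_nobody(self):
        densities = list(covnet.DENSITY_SWEEP[:4])
        rows = {d: [5.0, 5.0, 5.0, 5.0] for d in densities}
        hubs = covnet.identify_hubs(self._metrics_from_betweenness(rows))
        assert hubs.hubs == ()


class TestCommunities:
    def test_two_disconnected_triangles(self):
        adj = np.zeros((6, 6), bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[i, j] = adj[j, i] = True
        part = covnet.detect_communities(_graph(adj), seed=0, restarts=20)
        assert part.modularity == pytest.approx(0.5)
        labels = part.labels
        assert labels.iloc[0] == labels.iloc[1] == labels.iloc[2]
        assert labels.iloc[3] == labels.iloc[4] == labels.iloc[5]
        assert labels.iloc[0] != labels.iloc[3]

    def test_bridged_triangles(self):
        adj = np.zeros((6, 6), bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
            adj[i, j] = adj[j, i] = True
        part = covnet.detect_communities(_graph(adj), seed=0, restarts=20)
        assert part.modularity == pytest.approx(2 * (3 / 7 - 0.25), abs=1e-9)

    def test_complete_graph_nonnegative_q(self):
        adj = ~np.eye(5, dtype=bool)
        part = covnet.detect_communities(_graph(adj), seed=0, restarts=10)
        assert part.modularity >= 0.0

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if G.number_of_edges() == 0:
                continue
            adj = nx.to_numpy_array(G).astype(bool)
            part = covnet.detect_communities(_graph(adj), seed=1, restarts=30)
            best = exhaustive_best_modularity(G)
            assert part.modularity <= best + 1e-9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            covnet.detect_communities(_graph(np.zeros((4, 4), bool)))

    def test_labels_canonical_by_size(self):
        adj = np.zeros((7, 7), bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (2, 3), (4, 5), (5, 6), (4, 6)]:
            adj[i, j] = adj[j, i] = True
        part = covnet.detect_communities(_graph(adj), seed=0, restarts=20)
        sizes = part.labels.value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)


@pytest.fixture(scope="module")
def split_population(atlas68):
    """One homogeneous population arbitrarily split into two groups."""
    truth = synthio.default_truth(
        atlas68, sites=("siteA",), site_shift_sd=0.0, site_scale_sd=1e-9,
        seed=6,
    )
    truth.delta = np.zeros(68)
    truth.loadings["noVH"] = truth.loadings["VH"]
    table, meta = synthio.generate_cohort(atlas68, truth, 60, seed=7)
    resid = covnet.residualize(table, meta, ("age", "gender"),
                               homogeneity_check=False)
    return resid, meta


@pytest.fixture(scope="module")
def modular_cohort(atlas68):
    truth = synthio.default_truth(
        atlas68, sites=("siteA",), site_shift_sd=0.0, site_scale_sd=1e-9,
        seed=8,
    )
    table, meta = synthio.generate_cohort(atlas68, truth, 150, seed=9)
    resid = covnet.residualize(table, meta, ("age", "gender"),
                               homogeneity_check=False)
    return resid, meta


class TestPermutationTests:
    def test_null_calibration(self, split_population):
        resid, meta = split_population
        res = covnet.permutation_test_metrics(
            resid, meta, n_perm=200, densities=(0.10, 0.16), seed=0,
            metrics=("degree", "betweenness"),
        )
        sig = res.groupby("metric")["p_fdr"].apply(lambda p: (p < 0.05).sum())
        assert int(sig.sum()) == 0
        # raw p-values roughly uniform: mean near 0.5
        assert 0.35 < res["p"].mean() < 0.65

    def test_small_n_perm_refused(self, split_population):
        resid, meta = split_population
        with pytest.raises(ValidationError):
            covnet.permutation_test_metrics(resid, meta, n_perm=50)

    def test_extreme_statistic_minimal_p(self):
        """A difference larger than every null draw gets p = 1/(n_perm+1)."""
        p_min = (1.0 + 0) / (1.0 + 200)
        assert p_min == pytest.approx(1.0 / 201.0)


class TestBootstrapModularity:
    def test_ci_shrinks_with_n(self, atlas68):
        truth = synthio.default_truth(
            atlas68, sites=("siteA",), site_shift_sd=0.0, site_scale_sd=1e-9,
            seed=8,
        )
        widths = []
        for n in (50, 200, 800):
            table, meta = synthio.generate_cohort(atlas68, truth, n, seed=10)
            resid = covnet.residualize(table, meta, ("age", "gender"),
                                       homogeneity_check=False)
            boot = covnet.bootstrap_modularity(
                resid, meta, GROUP_VH, reps=60, seed=0, restarts=3
            )
            widths.append(boot["ci"][1] - boot["ci"][0])
        assert widths[0] > widths[1] > widths[2]

    def test_single_rep_degenerate(self, modular_cohort):
        resid, meta = modular_cohort
        with pytest.warns(UserWarning, match="SD undefined"):
            boot = covnet.bootstrap_modularity(
                resid, meta, GROUP_VH, reps=1, seed=0, restarts=3
            )
        assert boot["sd"] == 0.0

    def test_deterministic_given_seed(self, modular_cohort):
        resid, meta = modular_cohort
        b1 = covnet.bootstrap_modularity(resid, meta, GROUP_VH, reps=30,
                                         seed=4, restarts=3)
        b2 = covnet.bootstrap_modularity(resid, meta, GROUP_VH, reps=30,
                                         seed=4, restarts=3)
        assert b1 == b2


class TestCorrelateDiffMetrics:
    def test_proportional_vectors_r_signed_one(self):
        idx = [f"r{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        d = pd.Series(rng.standard_normal(20), index=idx)
        res = covnet.correlate_diff_metrics(
            d, {"nodal_efficiency": -2.0 * d}, n_boot=200, seed=0
        )
        assert res["r"].iloc[0] == pytest.approx(-1.0)

    def test_standardized_slope_equals_r(self):
        idx = [f"r{i}" for i in range(60)]
        rng = np.random.default_rng(1)
        x = pd.Series(rng.standard_normal(60), index=idx)
        y = pd.Series(0.5 * x.to_numpy() + rng.standard_normal(60), index=idx)
        res = covnet.correlate_diff_metrics(y, {"m": x}, n_boot=200, seed=0)
        beta_std = res["slope"].iloc[0] * x.std(ddof=1) / y.std(ddof=1)
        assert abs(beta_std - res["r"].iloc[0]) < 1e-12

    def test_null_type_one_error(self):
        idx = [f"r{i}" for i in range(148)]
        rej = 0
        trials = 300
        for s in range(trials):
            rng = np.random.default_rng(s)
            d = pd.Series(rng.standard_normal(148), index=idx)
            m = pd.Series(rng.standard_normal(148), index=idx)
            res = covnet.correlate_diff_metrics(d, {"m": m}, n_boot=2, seed=0)
            rej += res["p"].iloc[0] < 0.05
        assert 0.02 < rej / trials < 0.09

    def test_zero_variance_rejected(self):
        idx = [f"r{i}" for i in range(10)]
        d = pd.Series(np.arange(10.0), index=idx)
        with pytest.raises(ValidationError):
            covnet.correlate_diff_metrics(d, {"m": pd.Series(np.ones(10), index=idx)})
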