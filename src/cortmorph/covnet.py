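"""Structural covariance networks and their group comparison.

Morphometric values are residualised on nuisance covariates (age and
gender by default) within the full sample; each group's network is the
matrix of inter-regional Pearson correlations of those residuals.
Networks are compared edge-wise (Fisher z test for two independent
correlations, BH-FDR over all unordered pairs) and as binary graphs
obtained by density thresholding: at density d the k = round(d*R(R-1)/2)
most positive correlations become edges, over the sweep d = 0.05..0.20
in 0.01 steps. Node metrics (degree, betweenness centrality, nodal and
local efficiency), a betweenness hub rule (mean + 1 SD at >= half the
densities), Louvain communities/modularity, label-permutation tests and
a within-group modularity bootstrap complete the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .groupstats import bh_adjust
from .harmonize import design_matrix
from .types import GROUP_NOVH, GROUP_VH, MorphometricTable, ValidationError

#: the study's density sweep: 0.05 to 0.20 in 0.01 steps (16 densities)
DENSITY_SWEEP = tuple(np.round(np.arange(0.05, 0.2001, 0.01), 2))

DEFAULT_COVARIATES = ("age", "gender")


# ---------------------------------------------------------------------------
# residualisation and covariance
# ---------------------------------------------------------------------------

def residualize(
    table: MorphometricTable,
    meta: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    homogeneity_check: bool = True,
) -> MorphometricTable:
    """Per-region OLS residuals on the covariates, full-sample fit.

    A Brown-Forsythe (Levene) homogeneity check of the residual
    variances between groups is run per region and reported as a warning
    only, mirroring the study's QC step.
    """
    meta = meta.set_index("subject_id").loc[table.subjects].reset_index()
    X = design_matrix(meta, covariates, add_intercept=True).to_numpy(float)
    Y = table.to_numpy()
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    if homogeneity_check and "group" in meta.columns:
        vh = (meta["group"] == GROUP_VH).to_numpy()
        nv = (meta["group"] == GROUP_NOVH).to_numpy()
        if vh.sum() >= 3 and nv.sum() >= 3:
            pvals = np.array(
                [
                    stats.levene(resid[vh, j], resid[nv, j], center="median")[1]
                    for j in range(resid.shape[1])
                ]
            )
            frac = float(np.mean(pvals < 0.05))
            if frac > 0.10:
                warnings.warn(
                    f"variance homogeneity questionable: Levene p<0.05 in "
                    f"{frac:.0%} of regions"
                )
    return table.copy_with(resid)


@dataclass
class CovarianceMatrix:
    """One group's residual-correlation (structural covariance) matrix."""

    group_label: str
    r: pd.DataFrame          # regions x regions Pearson correlations
    n_subjects: int
    covariates: tuple = ()

    def __post_init__(self):
        arr = self.r.to_numpy(float)
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if np.any(np.abs(arr) > 1 + 1e-10):
            raise ValidationError("|r| must be <= 1")

    @property
    def regions(self) -> list:
        return list(self.r.index)

    def values(self) -> np.ndarray:
        return self.r.to_numpy(float)


def covariance_matrix(
    residuals: MorphometricTable,
    meta: pd.DataFrame,
    group: str,
    covariates=DEFAULT_COVARIATES,
) -> CovarianceMatrix:
    """Inter-regional Pearson correlations of one group's residuals."""
    meta = meta.set_index("subject_id").loc[residuals.subjects].reset_index()
    sel = (meta["group"] == group).to_numpy()
    n = int(sel.sum())
    if n < 10:
        raise ValidationError(f"group {group!r} has n={n} < 10")
    Y = residuals.to_numpy()[sel]
    sd = Y.std(axis=0)
    if np.any(sd == 0):
        bad = [residuals.regions[j] for j in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant regions within group {group!r}: {bad}")
    r = np.corrcoef(Y, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CovarianceMatrix(
        group_label=group,
        r=pd.DataFrame(r, index=residuals.regions, columns=residuals.regions),
        n_subjects=n,
        covariates=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# edge-wise comparison
# ---------------------------------------------------------------------------

def _fisher_z(r: np.ndarray) -> np.ndarray:
    clipped = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    if np.any(np.abs(r) >= 1):
        warnings.warn("|r|=1 clamped to 1-1e-12 for the Fisher transform")
    return np.arctanh(clipped)


def compare_edges(cov_a: CovarianceMatrix, cov_b: CovarianceMatrix) -> pd.DataFrame:
    """Fisher z comparison of every unordered region pair across groups.

    z = (z_a - z_b) / sqrt(1/(n_a-3) + 1/(n_b-3)), two-sided normal p,
    BH-FDR over all pairs. ``delta_r2 = r_a^2 - r_b^2`` is reported; the
    |delta_r2| > 0.3 display rule is a visualisation filter only and is
    not applied here.
    """
    if cov_a.regions != cov_b.regions:
        raise ValidationError("covariance matrices cover different regions")
    R = len(cov_a.regions)
    iu = np.triu_indices(R, k=1)
    ra = cov_a.values()[iu]
    rb = cov_b.values()[iu]
    se = np.sqrt(1.0 / (cov_a.n_subjects - 3) + 1.0 / (cov_b.n_subjects - 3))
    z = (_fisher_z(ra) - _fisher_z(rb)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    labels = np.asarray(cov_a.regions)
    return pd.DataFrame(
        {
            "region_a": labels[iu[0]],
            "region_b": labels[iu[1]],
            f"r_{cov_a.group_label}": ra,
            f"r_{cov_b.group_label}": rb,
            "z": z,
            "p": p,
            "p_fdr": bh_adjust(p),
            "delta_r2": ra**2 - rb**2,
        }
    )


# ---------------------------------------------------------------------------
# density thresholding
# ---------------------------------------------------------------------------

@dataclass
class ThresholdedGraph:
    """Binary undirected graph keeping the most positive correlations."""

    density: float
    adjacency: np.ndarray     # (R, R) bool, no self-loops
    k: int                    # realised edge count
    group_label: str
    regions: list

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency.astype(int))
        return nx.relabel_nodes(G, dict(enumerate(self.regions)))


def _top_k_adjacency(r: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Adjacency of the k most positive off-diagonal correlations.

    Ties broken by lexicographic (i, j) pair order; negative or zero
    correlations are never included, even if k is not met.
    """
    R = r.shape[0]
    iu = np.triu_indices(R, k=1)
    vals = r[iu]
    pos = vals > 0
    order = np.lexsort((iu[1], iu[0], -vals))  # r desc, then (i, j) asc
    order = order[pos[order]]
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} positive correlations available for k={k}"
        )
    chosen = order[:k]
    adj = np.zeros((R, R), dtype=bool)
    adj[iu[0][chosen], iu[1][chosen]] = True
    return adj | adj.T, len(chosen)


def threshold_graph(cov: CovarianceMatrix, density: float) -> ThresholdedGraph:
    """Keep the top d * R(R-1)/2 most positive correlations as edges.

    k uses round-half-even on the pair count. Densities outside the
    study sweep [0.05, 0.20] are allowed with a warning.
    """
    if not 0.0 < density < 1.0:
        raise ValidationError("density must be in (0, 1)")
    if not (DENSITY_SWEEP[0] - 1e-9 <= density <= DENSITY_SWEEP[-1] + 1e-9):
        warnings.warn(
            f"density {density} outside the study sweep "
            f"[{DENSITY_SWEEP[0]}, {DENSITY_SWEEP[-1]}]"
        )
    r = cov.values()
    R = r.shape[0]
    k = int(np.round(density * R * (R - 1) / 2.0))
    adj, realised = _top_k_adjacency(r, k)
    return ThresholdedGraph(
        density=float(density),
        adjacency=adj,
        k=realised,
        group_label=cov.group_label,
        regions=cov.regions,
    )


# ---------------------------------------------------------------------------
# node and graph metrics
# ---------------------------------------------------------------------------

@dataclass
class NodeMetrics:
    """Per-node metrics of one thresholded graph plus graph-level values."""

    per_node: pd.DataFrame    # degree, betweenness, nodal/local efficiency
    global_efficiency: float
    density: float
    group_label: str
    modularity: float | None = None


def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj.astype(np.int8)), unweighted=True)


def _nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0  # disconnected pairs contribute 0
    n = dist.shape[0]
    return inv.sum(axis=1) / (n - 1)


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    return float(_nodal_efficiency(_distances(adj)).mean())


def _local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        out[i] = _global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return out


def node_metrics(graph: ThresholdedGraph) -> NodeMetrics:
    """Degree, betweenness (unnormalised counts), nodal and local
    efficiency per node; global efficiency per graph.

    Betweenness uses the unnormalised shortest-path count convention with
    fractional attribution over equal-length paths; the hub rule depends
    only on within-density ranking, which is convention-invariant.
    """
    adj = graph.adjacency
    G = nx.from_numpy_array(adj.astype(int))
    betw = nx.betweenness_centrality(G, normalized=False)
    dist = _distances(adj)
    per_node = pd.DataFrame(
        {
            "degree": adj.sum(axis=1).astype(int),
            "betweenness": [betw[i] for i in range(adj.shape[0])],
            "nodal_efficiency": _nodal_efficiency(dist),
            "local_efficiency": _local_efficiency(adj),
        },
        index=graph.regions,
    )
    return NodeMetrics(
        per_node=per_node,
        global_efficiency=float(_nodal_efficiency(dist).mean()),
        density=graph.density,
        group_label=graph.group_label,
    )


def metrics_across_densities(
    cov: CovarianceMatrix, densities=DENSITY_SWEEP
) -> dict:
    """Node metrics of one group's network at every density of the sweep."""
    return {float(d): node_metrics(threshold_graph(cov, d)) for d in densities}


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

@dataclass
class HubSet:
    """Nodes qualifying as betweenness hubs over the density sweep."""

    hubs: tuple
    qualification: pd.DataFrame  # densities x nodes, bool
    threshold: int               # densities needed to qualify
    group_label: str


def identify_hubs(metrics_by_density: dict, group_label: str = "") -> HubSet:
    """Betweenness hub rule over the density sweep.

    A node qualifies at one density when its betweenness exceeds the
    mean + 1 SD over all nodes at that density (strict inequality, so a
    zero-variance density qualifies nobody); a hub qualifies at at least
    ceil(n_densities / 2) densities — 8 of the study's 16.
    """
    if len(metrics_by_density) < 2:
        raise ValidationError("hub rule needs metrics at >= 2 densities")
    rows = {}
    for d, nm in sorted(metrics_by_density.items()):
        b = nm.per_node["betweenness"]
        rows[d] = b > (b.mean() + b.std(ddof=1))
    qual = pd.DataFrame(rows).T  # densities x nodes
    need = int(np.ceil(len(qual) / 2.0))
    counts = qual.sum(axis=0)
    hubs = tuple(counts.index[counts >= need])
    return HubSet(
        hubs=hubs, qualification=qual, threshold=need, group_label=group_label
    )


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Best-of-restarts Louvain partition of one thresholded graph."""

    labels: pd.Series   # community id per node, ids ordered by size
    modularity: float
    seed: int
    restarts: int


def _louvain_level(A: np.ndarray, rng, max_sweeps: int = 100) -> np.ndarray:
    """One Louvain level: greedy local moves until no gain.

    ``A`` is the symmetric weight matrix (diagonal = twice the self-loop
    weight, as produced by aggregation). Moves require a strictly
    positive modularity gain above a small tolerance and sweeps are
    capped, so floating-point oscillations cannot loop forever.
    """
    n = A.shape[0]
    m2 = A.sum()  # 2m
    k = A.sum(axis=1)
    labels = np.arange(n)
    sigma_tot = k.copy()
    for _ in range(max_sweeps):
        moved = False
        for u in rng.permutation(n):
            cu = labels[u]
            sigma_tot[cu] -= k[u]
            # weight from u to each community (excluding u itself)
            w = np.zeros(n)
            row = A[u].copy()
            row[u] = 0.0
            np.add.at(w, labels, row)
            gain = w / m2 - k[u] * sigma_tot / (m2 * m2)
            best = int(np.argmax(gain))  # ties -> lowest community id
            if gain[best] > gain[cu] + 1e-12:
                labels[u] = best
                moved = True
            sigma_tot[labels[u]] += k[u]
        if not moved:
            break
    # compact labels
    _, compact = np.unique(labels, return_inverse=True)
    return compact


def _louvain_once(A: np.ndarray, rng) -> np.ndarray:
    """Full multi-level Louvain on a weight matrix; returns node labels."""
    n = A.shape[0]
    membership = np.arange(n)
    work = A.astype(float).copy()
    while True:
        labels = _louvain_level(work, rng)
        n_comm = labels.max() + 1
        if n_comm == work.shape[0]:
            break
        membership = labels[membership]
        S = np.zeros((n_comm, work.shape[0]))
        S[labels, np.arange(work.shape[0])] = 1.0
        work = S @ work @ S.T  # diagonal becomes 2x internal weight
    return membership


def detect_communities(
    graph: ThresholdedGraph, seed: int = 0, restarts: int = 100
) -> Partition:
    """Louvain community detection, keeping the max-modularity partition.

    Runs ``restarts`` seeded Louvain passes (two-phase local moves +
    aggregation, authored here with a bounded sweep count) and keeps the
    best Newman-Girvan modularity; community labels are canonicalised by
    descending community size (ties by smallest member index).
    """
    if graph.adjacency.sum() == 0:
        raise ValidationError("cannot partition a graph with no edges")
    A = graph.adjacency.astype(float)
    G = graph.to_networkx()
    best_q, best_labels = -np.inf, None
    for i in range(restarts):
        rng = np.random.default_rng(seed + i)
        lab = _louvain_once(A, rng)
        comms = [
            {graph.regions[j] for j in np.flatnonzero(lab == c)}
            for c in range(lab.max() + 1)
        ]
        q = nx.community.modularity(G, comms)
        if q > best_q:
            best_q, best_labels = q, lab
    pos = np.arange(len(graph.regions))
    comms = [
        np.flatnonzero(best_labels == c) for c in range(best_labels.max() + 1)
    ]
    ordered = sorted(comms, key=lambda c: (-len(c), int(c.min())))
    labels = pd.Series(index=graph.regions, dtype=int, name="community")
    for cid, comm in enumerate(ordered):
        labels.iloc[comm] = cid
    return Partition(
        labels=labels, modularity=float(best_q), seed=seed, restarts=restarts
    )


# ---------------------------------------------------------------------------
# permutation and bootstrap inference
# ---------------------------------------------------------------------------

_PERM_METRICS = ("degree", "betweenness", "nodal_efficiency", "local_efficiency")


def _group_metric_stack(
    Y: np.ndarray, densities, regions
) -> dict:
    """metric -> (n_densities, n_nodes) array for one group's residuals."""
    r = np.corrcoef(Y, rowvar=False)
    cov = CovarianceMatrix(
        group_label="", r=pd.DataFrame(r, index=regions, columns=regions),
        n_subjects=Y.shape[0],
    )
    out = {m: [] for m in _PERM_METRICS}
    for d in densities:
        nm = node_metrics(threshold_graph(cov, d))
        for m in _PERM_METRICS:
            out[m].append(nm.per_node[m].to_numpy())
    return {m: np.asarray(v) for m, v in out.items()}


def permutation_test_metrics(
    residuals: MorphometricTable,
    meta: pd.DataFrame,
    n_perm: int = 5000,
    densities=DENSITY_SWEEP,
    seed: int = 0,
    mode: str = "per_density",
    metrics=_PERM_METRICS,
) -> pd.DataFrame:
    """Group-label permutation test of node-metric differences.

    The observed statistic is the VH - noVH difference of each node
    metric (per density, or averaged over the sweep with
    ``mode="averaged"``); the null rebuilds covariance -> threshold ->
    metric per label shuffle. p = (1 + #{|null| >= |obs|}) / (1 + n_perm)
    with BH-FDR over nodes (x densities in per-density mode), per metric.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if mode not in ("per_density", "averaged"):
        raise ValueError("mode must be 'per_density' or 'averaged'")
    meta = meta.set_index("subject_id").loc[residuals.subjects].reset_index()
    vh = (meta["group"] == GROUP_VH).to_numpy()
    nv = (meta["group"] == GROUP_NOVH).to_numpy()
    if vh.sum() < 10 or nv.sum() < 10:
        raise ValidationError("both groups need n >= 10")
    Y = residuals.to_numpy()
    regions = list(residuals.regions)
    densities = [float(d) for d in densities]

    def stat(mask_a, mask_b):
        a = _group_metric_stack(Y[mask_a], densities, regions)
        b = _group_metric_stack(Y[mask_b], densities, regions)
        diff = {m: a[m] - b[m] for m in metrics}
        if mode == "averaged":
            diff = {m: v.mean(axis=0, keepdims=True) for m, v in diff.items()}
        return diff

    obs = stat(vh, nv)
    rng = np.random.default_rng(seed)
    n_a = int(vh.sum())
    exceed = {m: np.zeros_like(obs[m]) for m in metrics}
    all_idx = np.arange(len(meta))
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        mask_a = np.zeros(len(meta), dtype=bool)
        mask_a[perm[:n_a]] = True
        null = stat(mask_a, ~mask_a)
        for m in metrics:
            exceed[m] += np.abs(null[m]) >= np.abs(obs[m])

    rows = []
    dens_out = densities if mode == "per_density" else ["averaged"]
    for m in metrics:
        p = (1.0 + exceed[m]) / (1.0 + n_perm)
        p_fdr = bh_adjust(p.ravel()).reshape(p.shape)
        for di, d in enumerate(dens_out):
            for ni, region in enumerate(regions):
                rows.append(
                    {
                        "metric": m, "density": d, "region_id": region,
                        "observed_diff": obs[m][di, ni],
                        "p": p[di, ni], "p_fdr": p_fdr[di, ni],
                    }
                )
    return pd.DataFrame(rows)


def bootstrap_modularity(
    residuals: MorphometricTable,
    meta: pd.DataFrame,
    group: str,
    density: float = 0.13,
    reps: int = 1000,
    seed: int = 0,
    restarts: int = 10,
) -> dict:
    """Within-group subject bootstrap of Louvain modularity.

    Resamples the group's subjects with replacement, rebuilds the
    covariance, thresholds at ``density`` and records the best-of-
    restarts Louvain Q. Returns mean, SD and the 95% percentile CI.
    """
    meta = meta.set_index("subject_id").loc[residuals.subjects].reset_index()
    sel = np.flatnonzero((meta["group"] == group).to_numpy())
    if sel.size < 10:
        raise ValidationError(f"group {group!r} has n < 10")
    Y = residuals.to_numpy()
    regions = list(residuals.regions)
    rng = np.random.default_rng(seed)
    qs = np.empty(reps)
    for b in range(reps):
        take = rng.choice(sel, size=sel.size, replace=True)
        Yb = Y[take]
        sd = Yb.std(axis=0)
        sd[sd == 0] = 1.0
        r = np.corrcoef(Yb, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
        cov = CovarianceMatrix(
            group_label=group,
            r=pd.DataFrame(r, index=regions, columns=regions),
            n_subjects=sel.size,
        )
        part = detect_communities(
            threshold_graph(cov, density),
            seed=int(rng.integers(2**31)),
            restarts=restarts,
        )
        qs[b] = part.modularity
    if reps == 1:
        warnings.warn("reps=1: SD undefined, reported as 0")
        return {"mean": float(qs[0]), "sd": 0.0, "ci": (float(qs[0]), float(qs[0])),
                "reps": 1, "density": density}
    return {
        "mean": float(qs.mean()),
        "sd": float(qs.std(ddof=1)),
        "ci": tuple(np.quantile(qs, [0.025, 0.975])),
        "reps": reps,
        "density": density,
    }


def correlate_diff_metrics(
    diffmap: pd.Series,
    metric_diffs: dict,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate the morphometric difference map with graph-metric
    differences (e.g. local and nodal efficiency).

    Pearson r with two-sided p, BH correction across the metric families
    tested, and an OLS of the morphometric difference on the metric
    difference with a percentile bootstrap CI for the slope.
    """
    from .receptormap import _bootstrap_slope_ci

    rows = []
    for name, md in metric_diffs.items():
        common = [r for r in diffmap.index if r in md.index]
        x = md.loc[common].to_numpy(float)
        y = diffmap.loc[common].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            raise ValidationError(f"zero-variance input for metric {name!r}")
        r, p = stats.pearsonr(x, y)
        xc = x - x.mean()
        slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
        ci = _bootstrap_slope_ci(x, y, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "metric": name, "r": float(r), "p": float(p),
                "slope": slope, "ci_lo": ci[0], "ci_hi": ci[1],
                "n": len(common),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"].to_numpy())
    return out
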