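"""Region screening, covariate-adjusted group comparison and sensitivity
analyses for the two-group (VH vs noVH) design.

The screening stage runs a per-region ANCOVA F-test for the group factor
with Benjamini-Hochberg FDR over all regions of one morphometric kind;
surviving regions enter a MANCOVA (Pillai's trace by default) with
Bonferroni-corrected pairwise group contrasts. Difference maps are
unadjusted VH - noVH means, the input to the receptor-association stage.
Sensitivity utilities mirror the rest of the study design: Tukey-fence
outlier flagging, group/sample-mean imputation, partial correlations with
symptom severity, random-effects meta-analysis of per-study differences,
and a leave-one-study-out robustness loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

from .harmonize import design_matrix
from .types import GROUP_NOVH, GROUP_VH, MorphometricTable, ValidationError

DEFAULT_COVARIATES = ("age", "gender", "tiv")

_STAT_ROW = {"pillai": "Pillai's trace", "wilks": "Wilks' lambda"}


# ---------------------------------------------------------------------------
# vectorised ANCOVA machinery
# ---------------------------------------------------------------------------

def _aligned_meta(table: MorphometricTable, meta: pd.DataFrame) -> pd.DataFrame:
    return meta.set_index("subject_id").loc[table.subjects].reset_index()


def _interaction_columns(meta: pd.DataFrame, interactions) -> pd.DataFrame:
    cols = {}
    for term in interactions:
        a, b = term.split(":")
        va = pd.to_numeric(meta[a]) if meta[a].dtype != object else (
            meta[a].astype(str) == sorted(meta[a].astype(str).unique())[-1]
        ).astype(float)
        vb = pd.to_numeric(meta[b]) if meta[b].dtype != object else (
            meta[b].astype(str) == sorted(meta[b].astype(str).unique())[-1]
        ).astype(float)
        cols[f"{a}:{b}"] = (va * vb).to_numpy(float)
    return pd.DataFrame(cols, index=meta.index)


def _ancova_design(meta, covariates, interactions=()):
    X = design_matrix(meta, covariates, add_intercept=True)
    if interactions:
        X = pd.concat([X, _interaction_columns(meta, interactions)], axis=1)
    return X


def group_ancova(
    Y: np.ndarray, meta: pd.DataFrame, covariates, interactions=()
) -> dict:
    """Per-column F-test of the group factor adjusting for covariates.

    Vectorised over columns (regions): the reduced and full designs are
    shared, so residual sums of squares come from two QR projections.
    Returns F, p, partial eta^2, the adjusted VH - noVH difference, and
    degrees of freedom.
    """
    group = (meta["group"] == GROUP_VH).to_numpy(float)
    if group.sum() == 0 or group.sum() == len(group):
        raise ValidationError("both groups must be present")
    Xr = _ancova_design(meta, covariates, interactions).to_numpy(float)
    Xf = np.column_stack([Xr, group])
    n, pf = Xf.shape

    Qr, _ = np.linalg.qr(Xr)
    Qf, _ = np.linalg.qr(Xf)
    total = np.sum(Y**2, axis=0)
    rss_r = total - np.sum((Qr.T @ Y) ** 2, axis=0)
    rss_f = total - np.sum((Qf.T @ Y) ** 2, axis=0)
    rss_r = np.maximum(rss_r, 0.0)
    rss_f = np.maximum(rss_f, 0.0)
    ss_effect = np.maximum(rss_r - rss_f, 0.0)
    df2 = n - pf
    var_total = Y.var(axis=0)
    constant = var_total <= 1e-30

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_effect / (rss_f / df2)
        eta2 = ss_effect / (ss_effect + rss_f)
    F[constant] = np.nan
    eta2[constant] = np.nan
    p = stats.f.sf(F, 1, df2)

    coef, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    adj_diff = coef[-1]  # group coded 1 = VH
    return {
        "F": F, "p": p, "partial_eta2": eta2, "adjusted_diff": adj_diff,
        "df": (1, df2), "constant": constant,
    }


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-aware)."""
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def screen_regions_anova(
    table: MorphometricTable,
    meta: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    q: float = 0.05,
) -> pd.DataFrame:
    """Exploratory per-region ANCOVA screen with BH-FDR at level ``q``.

    The FDR family is all (non-degenerate) regions of this one
    morphometric kind. Constant regions are reported with ``p = NaN`` and
    excluded from the family.
    """
    meta = _aligned_meta(table, meta)
    res = group_ancova(table.to_numpy(), meta, covariates)
    if res["constant"].any():
        skipped = [
            table.regions[i] for i in np.flatnonzero(res["constant"])
        ]
        warnings.warn(f"constant regions excluded from FDR family: {skipped}")
    p_fdr = bh_adjust(res["p"])
    out = pd.DataFrame(
        {
            "region_id": list(table.regions),
            "F": res["F"],
            "df1": res["df"][0],
            "df2": res["df"][1],
            "p": res["p"],
            "p_fdr": p_fdr,
            "partial_eta2": res["partial_eta2"],
            "direction": np.sign(res["adjusted_diff"]),
            "adjusted_diff": res["adjusted_diff"],
        }
    )
    out["significant"] = out["p_fdr"] < q
    return out


# ---------------------------------------------------------------------------
# MANCOVA
# ---------------------------------------------------------------------------

def _single_dv_tests(
    y: np.ndarray, meta: pd.DataFrame, covariates, interactions, statistic: str
) -> pd.DataFrame:
    """Term-deletion F-tests for the one-region model.

    With a single dependent variable Pillai's trace reduces to
    SSH/(SSH+SSE) (= partial eta^2) and Wilks' lambda to SSE/(SSH+SSE),
    both with the univariate F and p, so the multivariate table of a
    one-region model equals the univariate ANCOVA.
    """
    blocks = {"group": [(meta["group"] == GROUP_VH).to_numpy(float)]}
    for c in covariates:
        sub = design_matrix(meta, [c], add_intercept=False)
        blocks[c] = [sub[col].to_numpy(float) for col in sub.columns]
    inter = _interaction_columns(meta, interactions)
    for col in inter.columns:
        blocks[col] = [inter[col].to_numpy(float)]
    names = list(blocks)
    X_full = np.column_stack(
        [np.ones(len(meta))] + [v for name in names for v in blocks[name]]
    )
    n, p_full = X_full.shape
    Qf, _ = np.linalg.qr(X_full)
    total = float(y @ y)
    rss_full = total - float(np.sum((Qf.T @ y) ** 2))
    rows = []
    for name in names:
        keep = [np.ones(len(meta))]
        for other in names:
            if other != name:
                keep.extend(blocks[other])
        Xr = np.column_stack(keep)
        Qr, _ = np.linalg.qr(Xr)
        rss_r = total - float(np.sum((Qr.T @ y) ** 2))
        q = len(blocks[name])
        df2 = n - p_full
        ssh = max(rss_r - rss_full, 0.0)
        F = (ssh / q) / (rss_full / df2)
        p = float(stats.f.sf(F, q, df2))
        value = (
            ssh / (ssh + rss_full) if statistic == "pillai"
            else rss_full / (ssh + rss_full)
        )
        rows.append(
            {
                "term": name, "statistic": statistic, "value": value,
                "F": F, "df1": float(q), "df2": float(df2), "p": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MancovaResult:
    """Multivariate tests per model term plus per-region follow-up."""

    multivariate: pd.DataFrame   # term, statistic, value, F, df1, df2, p
    per_region: pd.DataFrame     # region_id, F, p, partial_eta2, direction
    pairwise: pd.DataFrame       # region_id, diff, p, p_bonferroni
    statistic: str
    regions: list
    covariates: list
    interactions: list


def fit_mancova(
    table: MorphometricTable,
    meta: pd.DataFrame,
    regions,
    covariates=DEFAULT_COVARIATES,
    interactions=(),
    statistic: str = "pillai",
) -> MancovaResult:
    """Multivariate group comparison over the selected regions.

    Pillai's trace by default (robust to covariance heterogeneity);
    Wilks' lambda available. Pairwise (two-group) contrasts are
    Bonferroni-corrected over the number of regions entered.
    """
    regions = list(regions)
    if not regions:
        raise ValidationError("regions must be nonempty")
    meta = _aligned_meta(table, meta)
    n = len(meta)
    n_cov_cols = _ancova_design(meta, covariates, interactions).shape[1] - 1
    if n <= len(regions) + n_cov_cols + 2:
        raise ValidationError(
            f"too few subjects ({n}) for {len(regions)} regions "
            f"and {n_cov_cols} covariate columns"
        )
    sub = table.values[regions]
    Y = sub.to_numpy(float)

    # singular within-group covariance check
    resid = np.concatenate(
        [
            Y[(meta["group"] == g).to_numpy()] -
            Y[(meta["group"] == g).to_numpy()].mean(axis=0)
            for g in (GROUP_VH, GROUP_NOVH)
        ]
    )
    W = resid.T @ resid
    if np.linalg.matrix_rank(W) < len(regions):
        raise ValidationError(
            "within-group covariance is singular; enter fewer regions"
        )

    if len(regions) == 1:
        multivariate = _single_dv_tests(
            Y[:, 0], meta, covariates, interactions, statistic
        )
    else:
        data = pd.DataFrame(
            Y, columns=[f"y{i}" for i in range(len(regions))], index=meta.index
        )
        data["group"] = meta["group"].to_numpy()
        rhs_terms = ["group"]
        for c in covariates:
            data[c] = meta[c].to_numpy()
            rhs_terms.append(c if data[c].dtype != object else f"C({c})")
        inter = _interaction_columns(meta, interactions)
        for i, c in enumerate(inter.columns):
            data[f"x{i}"] = inter[c].to_numpy()
            rhs_terms.append(f"x{i}")
        lhs = " + ".join(data.columns[: len(regions)])
        formula = f"{lhs} ~ " + " + ".join(rhs_terms)
        mv = MANOVA.from_formula(formula, data=data)
        raw = mv.mv_test()

        stat_row = _STAT_ROW[statistic]
        clean = {f"C({c})": c for c in covariates}
        rows = []
        for term in rhs_terms:
            if term not in raw.results:
                continue
            tab = raw.results[term]["stat"]
            r = tab.loc[stat_row]
            rows.append(
                {
                    "term": clean.get(term, term),
                    "statistic": statistic,
                    "value": float(r["Value"]),
                    "F": float(r["F Value"]),
                    "df1": float(r["Num DF"]),
                    "df2": float(r["Den DF"]),
                    "p": float(r["Pr > F"]),
                }
            )
        multivariate = pd.DataFrame(rows)

    uni = group_ancova(Y, meta, covariates, interactions)
    m = len(regions)
    p_bonf = np.minimum(1.0, m * uni["p"])
    per_region = pd.DataFrame(
        {
            "region_id": regions,
            "F": uni["F"],
            "p": uni["p"],
            "partial_eta2": uni["partial_eta2"],
            "direction": np.sign(uni["adjusted_diff"]),
        }
    )
    pairwise = pd.DataFrame(
        {
            "region_id": regions,
            "diff": uni["adjusted_diff"],
            "p": uni["p"],
            "p_bonferroni": p_bonf,
        }
    )
    return MancovaResult(
        multivariate=multivariate,
        per_region=per_region,
        pairwise=pairwise,
        statistic=statistic,
        regions=regions,
        covariates=list(covariates),
        interactions=list(interactions),
    )


# ---------------------------------------------------------------------------
# difference maps
# ---------------------------------------------------------------------------

@dataclass
class DifferenceMap:
    """Per-region unadjusted difference of group means (VH - noVH)."""

    frame: pd.DataFrame  # region_id, diff, se
    measure_kind: str = "thickness"

    @property
    def diff(self) -> pd.Series:
        return pd.Series(
            self.frame["diff"].to_numpy(), index=self.frame["region_id"]
        )

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            self.frame["se"].to_numpy(), index=self.frame["region_id"]
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, measure_kind="thickness") -> "DifferenceMap":
        return cls(pd.read_csv(path), measure_kind)


def compute_difference_map(
    table: MorphometricTable, meta: pd.DataFrame
) -> DifferenceMap:
    """VH minus noVH mean per region, with pooled-variance standard error."""
    meta = _aligned_meta(table, meta)
    Y = table.to_numpy()
    vh = (meta["group"] == GROUP_VH).to_numpy()
    nv = (meta["group"] == GROUP_NOVH).to_numpy()
    n1, n2 = int(vh.sum()), int(nv.sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    diff = Y[vh].mean(axis=0) - Y[nv].mean(axis=0)
    s2p = (
        (n1 - 1) * Y[vh].var(axis=0, ddof=1) + (n2 - 1) * Y[nv].var(axis=0, ddof=1)
    ) / (n1 + n2 - 2)
    se = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
    return DifferenceMap(
        pd.DataFrame(
            {"region_id": list(table.regions), "diff": diff, "se": se}
        ),
        table.measure_kind,
    )


# ---------------------------------------------------------------------------
# outliers, imputation, correlations
# ---------------------------------------------------------------------------

def flag_outliers_tukey(values) -> np.ndarray:
    """Indices outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation of order statistics.
    """
    values = np.asarray(values, float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        raise ValidationError("need >= 4 finite values for Tukey fences")
    q1, q3 = np.percentile(values[finite], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return np.flatnonzero(finite & ((values < lo) | (values > hi)))


def impute_group_mean(
    values, groups=None, mode: str = "sample"
) -> np.ndarray:
    """Fill missing entries with the mean of observed values.

    ``mode="sample"`` (default) uses the pooled mean of all observed
    entries; ``mode="group"`` uses the per-group mean of ``groups``.
    Observed entries are untouched.
    """
    values = np.asarray(values, float).copy()
    missing = ~np.isfinite(values)
    if not missing.any():
        return values
    if mode == "sample":
        if (~missing).sum() == 0:
            raise ValidationError("no observed values to impute from")
        values[missing] = values[~missing].mean()
        return values
    if mode != "group":
        raise ValueError("mode must be 'sample' or 'group'")
    if groups is None:
        raise ValidationError("group-mean imputation needs group labels")
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        sel = groups == g
        if missing[sel].any():
            obs = sel & ~missing
            if obs.sum() == 0:
                raise ValidationError(f"group {g!r} fully missing")
            values[sel & missing] = values[obs].mean()
    return values


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariate effects.

    Both variables are residualised on the covariates (with intercept);
    the p-value is two-sided with df = n - 2 - n_covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
    if n <= k + 3:
        raise ValidationError("need n > n_covariates + 3")
    Q, Rm = np.linalg.qr(Z)
    # drop degenerate directions (constant or collinear covariates)
    diag = np.abs(np.diag(Rm))
    Q = Q[:, diag > 1e-10 * max(diag.max(), 1.0)]
    rx = x - Q @ (Q.T @ x)
    ry = y - Q @ (Q.T @ y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValidationError("constant residuals; correlation undefined")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 2 - k
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        return r_, 0.0
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r_, float(p)


# ---------------------------------------------------------------------------
# meta-analysis and robustness
# ---------------------------------------------------------------------------

def meta_analyze(mean_diffs, variances) -> dict:
    """Random-effects pooling (DerSimonian-Laird) of per-study differences.

    Returns the pooled mean difference, its SE, the 95% Wald CI, tau^2
    and Cochran's Q. A single study degenerates to that study's estimate
    with tau^2 = 0 and a warning.
    """
    md = np.asarray(mean_diffs, float)
    v = np.asarray(variances, float)
    if np.any(v <= 0):
        raise ValidationError("study variances must be positive")
    k = len(md)
    if k < 1:
        raise ValidationError("no studies")
    if k == 1:
        warnings.warn("single study: meta-analysis degenerates to that study")
        se = float(np.sqrt(v[0]))
        return {
            "pooled": float(md[0]), "se": se,
            "ci": (md[0] - 1.959963984540054 * se, md[0] + 1.959963984540054 * se),
            "tau2": 0.0, "Q": 0.0, "k": 1,
        }
    w = 1.0 / v
    mu_fe = np.sum(w * md) / np.sum(w)
    Q = float(np.sum(w * (md - mu_fe) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / c)
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * md) / np.sum(w_re))
    se = float(1.0 / np.sqrt(np.sum(w_re)))
    z = 1.959963984540054
    return {
        "pooled": pooled, "se": se, "ci": (pooled - z * se, pooled + z * se),
        "tau2": float(tau2), "Q": Q, "k": k,
    }


def leave_one_study_out(
    table: MorphometricTable,
    meta: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    q: float = 0.05,
    with_mancova: bool = True,
) -> pd.DataFrame:
    """Re-run the screen (and MANCOVA) holding out each study in turn.

    Reports each run's flagged-region set and its Jaccard overlap with
    the full-sample flags. Deterministic: no randomness is involved.
    """
    meta = _aligned_meta(table, meta)
    sites = sorted(pd.unique(meta["site"]))
    if len(sites) < 3:
        raise ValidationError("leave-one-study-out needs >= 3 studies")
    full = screen_regions_anova(table, meta, covariates, q)
    full_set = set(full.loc[full["significant"], "region_id"])
    rows = []
    for s in sites:
        keep = (meta["site"] != s).to_numpy()
        sub_meta = meta.loc[keep].reset_index(drop=True)
        counts = sub_meta["group"].value_counts()
        if counts.reindex([GROUP_VH, GROUP_NOVH]).fillna(0).min() < 2:
            warnings.warn(f"run without {s} leaves <2 subjects in a group; skipped")
            continue
        sub = MorphometricTable(table.values.iloc[keep].copy(), table.measure_kind)
        res = screen_regions_anova(sub, sub_meta, covariates, q)
        flags = set(res.loc[res["significant"], "region_id"])
        union = full_set | flags
        jacc = len(full_set & flags) / len(union) if union else 1.0
        mv_p = np.nan
        if with_mancova and flags:
            try:
                mv = fit_mancova(sub, sub_meta, sorted(flags), covariates)
                grp = mv.multivariate.query("term == 'group'")
                mv_p = float(grp["p"].iloc[0]) if len(grp) else np.nan
            except ValidationError:
                mv_p = np.nan
        rows.append(
            {
                "held_out": s,
                "n_flagged": len(flags),
                "flagged": sorted(flags),
                "jaccard_vs_full": jacc,
                "mancova_group_p": mv_p,
            }
        )
    return pd.DataFrame(rows)


def compare_demographics(
    meta: pd.DataFrame,
    continuous=("age", "tiv", "led", "mmse", "updrs3", "onset"),
    categorical=("gender",),
    yates: bool = False,
    levene_center: str = "median",
) -> pd.DataFrame:
    """Group comparisons of demographic/clinical variables.

    One-way ANOVA and a Brown-Forsythe (median-centred) Levene test per
    continuous variable; chi-square (no continuity correction by
    default) per categorical variable. Chi-square is refused when an
    expected cell count is zero.
    """
    groups = [GROUP_VH, GROUP_NOVH]
    if not all((meta["group"] == g).any() for g in groups):
        raise ValidationError("both groups must be present")
    rows = []
    for var in continuous:
        if var not in meta.columns:
            continue
        samples = [
            pd.to_numeric(meta.loc[meta["group"] == g, var]).dropna().to_numpy()
            for g in groups
        ]
        F, p = stats.f_oneway(*samples)
        lev_s, lev_p = stats.levene(*samples, center=levene_center)
        rows.append(
            {
                "variable": var, "test": "anova", "statistic": float(F),
                "p": float(p), "levene_stat": float(lev_s),
                "levene_p": float(lev_p),
            }
        )
    for var in categorical:
        if var not in meta.columns:
            continue
        tab = pd.crosstab(meta["group"], meta[var])
        expected = stats.contingency.expected_freq(tab.to_numpy())
        if (expected == 0).any():
            warnings.warn(f"chi-square refused for {var}: zero expected cell")
            rows.append(
                {
                    "variable": var, "test": "chi2", "statistic": np.nan,
                    "p": np.nan, "levene_stat": np.nan, "levene_p": np.nan,
                }
            )
            continue
        chi2, p, *_ = stats.chi2_contingency(tab, correction=yates)
        rows.append(
            {
                "variable": var, "test": "chi2", "statistic": float(chi2),
                "p": float(p), "levene_stat": np.nan, "levene_p": np.nan,
            }
        )
    return pd.DataFrame(rows)
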