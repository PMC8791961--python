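"""Receptor-density associations with group difference maps.

Relates a per-region difference-of-means map (VH - noVH) to parcellated
PET binding-potential maps (e.g. D2/D3, 5-HT1A, 5-HT2A templates with
the cerebellum as reference region, hence cerebellar parcels excluded).
Three fits per receptor mirror the study design: significant regions,
all regions, non-significant regions. Inference is by OLS with Cook's
distance influence screening and percentile-bootstrap CIs, and by a
spatial-autocorrelation-aware spin permutation test that randomly
rotates parcel centroids on the sphere (mirrored rotations per
hemisphere) and reassigns regions to their nearest original position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import Atlas, ValidationError

SUBSET_LABELS = ("significant", "all", "nonsignificant")


@dataclass
class ReceptorMap:
    """Per-region binding potential (dimensionless, reference-region model)."""

    bp: pd.Series
    receptor_label: str = "receptor"
    excluded_regions: tuple = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.bp.to_numpy(float))):
            raise ValidationError("binding potential must be finite")

    def usable(self) -> pd.Series:
        """Binding values minus the excluded (e.g. cerebellar) parcels."""
        return self.bp.drop(labels=[r for r in self.excluded_regions
                                    if r in self.bp.index])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"region_id": self.bp.index, "bp": self.bp.to_numpy()}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, receptor_label="receptor", excluded_regions=()):
        df = pd.read_csv(path)
        return cls(
            pd.Series(df["bp"].to_numpy(float), index=df["region_id"], name="bp"),
            receptor_label,
            tuple(excluded_regions),
        )


@dataclass
class AssociationResult:
    """One receptor-vs-difference regression fit."""

    receptor_label: str
    subset_label: str
    beta_std: float
    slope: float
    t: float
    p: float
    ci: tuple
    n_regions: int
    outliers_removed: tuple
    initial: dict | None = None  # pre-removal fit when points were dropped

    def as_dict(self) -> dict:
        return {
            "receptor_label": self.receptor_label,
            "subset_label": self.subset_label,
            "beta_std": self.beta_std,
            "slope": self.slope,
            "t": self.t,
            "p": self.p,
            "ci": list(self.ci),
            "n_regions": self.n_regions,
            "outliers_removed": list(self.outliers_removed),
            "initial": self.initial,
        }


def align_receptor_map(
    rmap: ReceptorMap,
    diff: pd.Series,
    atlas: Atlas | None = None,
    subset=None,
) -> tuple[pd.Series, pd.Series, list]:
    """Label-keyed pairing of difference and binding values.

    Takes the intersection of the map, the difference map, the optional
    ``subset`` filter and (if given) the atlas regions, minus the map's
    excluded parcels. Order-independent: output is sorted by atlas order
    when an atlas is given, by label otherwise. Returns
    ``(diff_aligned, bp_aligned, dropped_labels)``.
    """
    bp = rmap.usable()
    labels = set(bp.index) & set(diff.index)
    if subset is not None:
        labels &= set(subset)
    if atlas is not None:
        labels &= set(atlas.region_id)
        order = [r for r in atlas.region_id if r in labels]
    else:
        order = sorted(labels)
    if not order:
        raise ValidationError(
            "no overlapping regions between difference map "
            f"({len(diff)}) and receptor map ({len(bp)}) after exclusions"
        )
    dropped = sorted((set(bp.index) | set(diff.index)) - labels)
    return diff.loc[order], bp.loc[order], dropped


def _bootstrap_slope_ci(
    x: np.ndarray, y: np.ndarray, n_boot: int, seed: int, level: float = 0.95
) -> tuple:
    """Percentile bootstrap CI for the OLS slope, vectorised over draws."""
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sum(xc**2, axis=1)
    ok = denom > 0
    slopes = np.full(n_boot, np.nan)
    slopes[ok] = np.sum(xc * yc, axis=1)[ok] / denom[ok]
    slopes = slopes[np.isfinite(slopes)]
    a = (1.0 - level) / 2.0
    return tuple(np.quantile(slopes, [a, 1.0 - a]))


def fit_receptor_regression(
    diff: pd.Series,
    rmap: ReceptorMap,
    atlas: Atlas | None = None,
    subset=None,
    subset_label: str = "all",
    remove_influential: bool = True,
    cooks_threshold: float = 1.0,
    n_boot: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """OLS of the difference map on binding potential.

    Reports the standardized slope (equal to Pearson r for this simple
    regression), Cook's-distance influential points (D > 1 by default;
    refit without them when ``remove_influential``), and a seeded
    percentile bootstrap CI for the unstandardized slope.
    """
    d, bp, _ = align_receptor_map(rmap, diff, atlas, subset)
    x = bp.to_numpy(float)
    y = d.to_numpy(float)
    if len(x) < 8:
        raise ValidationError("need >= 8 paired regions")
    if x.std() == 0:
        raise ValidationError("zero-variance predictor")

    def _fit(xv, yv):
        X = sm.add_constant(xv)
        model = sm.OLS(yv, X).fit()
        slope = float(model.params[1])
        sy = yv.std(ddof=1)
        beta_std = slope * xv.std(ddof=1) / sy if sy > 0 else np.nan
        return model, slope, beta_std

    model, slope, beta_std = _fit(x, y)
    cooks = model.get_influence().cooks_distance[0]
    influential = np.flatnonzero(cooks > cooks_threshold)
    initial = None
    labels_removed = ()
    if remove_influential and influential.size:
        if influential.size >= len(x) - 2:
            warnings.warn("all points influential; keeping the initial fit")
        else:
            initial = {
                "beta_std": beta_std, "slope": slope,
                "t": float(model.tvalues[1]), "p": float(model.pvalues[1]),
            }
            labels_removed = tuple(np.asarray(d.index)[influential])
            keep = np.setdiff1d(np.arange(len(x)), influential)
            x, y = x[keep], y[keep]
            model, slope, beta_std = _fit(x, y)
    ci = _bootstrap_slope_ci(x, y, n_boot=n_boot, seed=seed)
    return AssociationResult(
        receptor_label=rmap.receptor_label,
        subset_label=subset_label,
        beta_std=float(beta_std),
        slope=slope,
        t=float(model.tvalues[1]),
        p=float(model.pvalues[1]),
        ci=ci,
        n_regions=len(x),
        outliers_removed=labels_removed,
        initial=initial,
    )


def fit_receptor_subsets(
    diff: pd.Series,
    rmap: ReceptorMap,
    significant_regions,
    atlas: Atlas | None = None,
    **kwargs,
) -> dict:
    """The study's three fits: significant / all / non-significant regions."""
    sig = [r for r in significant_regions if r in diff.index]
    nonsig = [r for r in diff.index if r not in set(sig)]
    out = {}
    for label, sub in (
        ("significant", sig), ("all", None), ("nonsignificant", nonsig)
    ):
        try:
            out[label] = fit_receptor_regression(
                diff, rmap, atlas, subset=sub, subset_label=label, **kwargs
            )
        except ValidationError as err:
            warnings.warn(f"subset {label}: {err}")
    return out


def compare_slopes(
    res_a: AssociationResult,
    res_b: AssociationResult,
    diff: pd.Series,
    map_a: ReceptorMap,
    map_b: ReceptorMap,
    atlas: Atlas | None = None,
    subset=None,
) -> tuple[float, float]:
    """Interaction test for equality of two receptors' slopes.

    Stacks the two standardized predictors against the shared outcome and
    tests the predictor x receptor-indicator interaction (two-sided t).
    Both fits must model the same outcome over the same region subset.
    """
    if res_a.subset_label != res_b.subset_label:
        raise ValidationError("fits must use the same region subset/outcome")
    d_a, bp_a, _ = align_receptor_map(map_a, diff, atlas, subset)
    d_b, bp_b, _ = align_receptor_map(map_b, diff, atlas, subset)
    if list(d_a.index) != list(d_b.index):
        raise ValidationError("receptor maps cover different regions")
    xa = stats.zscore(bp_a.to_numpy(float), ddof=1)
    xb = stats.zscore(bp_b.to_numpy(float), ddof=1)
    y = np.concatenate([d_a.to_numpy(float), d_b.to_numpy(float)])
    x = np.concatenate([xa, xb])
    ind = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    X = sm.add_constant(np.column_stack([x, ind, x * ind]))
    model = sm.OLS(y, X).fit()
    return float(model.tvalues[3]), float(model.pvalues[3])


# ---------------------------------------------------------------------------
# spin permutations
# ---------------------------------------------------------------------------

@dataclass
class SpinNull:
    """Stack of rotation-based region permutations for one atlas."""

    permutations: np.ndarray  # (n_spins, n_regions) int
    atlas_hash: str
    n_spins: int = field(init=False)

    def __post_init__(self):
        self.n_spins = self.permutations.shape[0]
        R = self.permutations.shape[1]
        ref = np.arange(R)
        for row in self.permutations:
            if not np.array_equal(np.sort(row), ref):
                raise ValidationError("spin rows must be permutations")


def _atlas_hash(atlas: Atlas) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.round(atlas.centroid, 12)).tobytes())
    h.update("|".join(atlas.region_id).encode())
    return h.hexdigest()[:16]


def _random_rotation(rng) -> np.ndarray:
    """Uniform random 3D rotation via orthonormalised Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(Rm))  # unique QR -> Haar distributed
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return Q


def _greedy_match(rotated: np.ndarray, original: np.ndarray) -> np.ndarray:
    """Greedy minimal-angular-distance assignment, lowest-index tie-break.

    Returns ``assign`` with ``assign[i] = j``: original position i takes
    the value of region j after the spin.
    """
    cosine = np.clip(rotated @ original.T, -1.0, 1.0)
    dist = np.arccos(cosine)  # rows: rotated region j, cols: original slot i
    n = dist.shape[0]
    assign = np.full(n, -1, dtype=int)
    work = dist.copy()
    for _ in range(n):
        flat = np.argmin(work)  # ties: first (lowest) flat index
        j, i = np.unravel_index(flat, work.shape)
        assign[i] = j
        work[j, :] = np.inf
        work[:, i] = np.inf
    return assign


def generate_spin_permutations(
    atlas: Atlas, n_spins: int, seed: int
) -> SpinNull:
    """Rotation-based spatial permutations of a symmetric atlas.

    Per spin, a uniform random rotation is applied to left-hemisphere
    centroids and its x-mirrored counterpart to the right hemisphere;
    each rotated region is then reassigned to the nearest original
    centroid within its hemisphere by greedy minimal-angular-distance
    matching. Requires a symmetric atlas (equal counts per hemisphere
    with mirror pairing) — the permutation scheme is undefined otherwise.
    """
    if not atlas.is_symmetric:
        raise ValidationError(
            "spin permutations require a symmetric atlas "
            "(equal region counts per hemisphere, mirror pairing defined)"
        )
    rng = np.random.default_rng(seed)
    left = atlas.indices("L")
    right = atlas.indices("R")
    M = np.diag([-1.0, 1.0, 1.0])
    perms = np.empty((n_spins, atlas.n_regions), dtype=int)
    cl = atlas.centroid[left]
    cr = atlas.centroid[right]
    for k in range(n_spins):
        Q = _random_rotation(rng)
        Qm = M @ Q @ M  # mirrored rotation for the right hemisphere
        al = _greedy_match(cl @ Q.T, cl)
        ar = _greedy_match(cr @ Qm.T, cr)
        row = np.empty(atlas.n_regions, dtype=int)
        row[left] = left[al]
        row[right] = right[ar]
        perms[k] = row
    return SpinNull(permutations=perms, atlas_hash=_atlas_hash(atlas))


def spin_correlation_test(
    diff: np.ndarray | pd.Series,
    rmap: np.ndarray | pd.Series,
    spins: SpinNull,
) -> tuple[float, float]:
    """Spatial-permutation p-value for the map correlation.

    Observed Pearson r between the two maps (aligned to atlas order);
    the null distribution correlates the difference map with each spun
    copy of the receptor map. Two-sided:
    ``p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_spins)``.
    """
    x = np.asarray(diff, float)
    y = np.asarray(rmap, float)
    if x.shape != y.shape or len(x) != spins.permutations.shape[1]:
        raise ValidationError("maps must align with the spin permutations")
    if spins.n_spins < 100:
        warnings.warn("fewer than 100 spins: p-value will be unstable")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    n = len(x)
    r_obs = float(xz @ yz / n)
    spun = yz[spins.permutations]          # (n_spins, n)
    r_null = spun @ xz / n
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (1.0 + spins.n_spins)
    return r_obs, float(p)
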