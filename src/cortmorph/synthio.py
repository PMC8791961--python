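"""Synthetic atlases, cohorts and receptor maps with known ground truth.

Real multi-site clinical morphometry cannot be redistributed, so every
stage of the pipeline is exercised on synthetic data that reproduces the
statistical structure the analysis assumes: per-site additive and
multiplicative scanner effects, a region-sparse group effect (cortical
thinning in the hallucinating group), covariate effects (age, gender,
head size), group-dependent inter-regional covariance induced by latent
factors, and receptor-like spatial maps with controllable smoothness and
controllable correlation to the planted difference map.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GROUP_NOVH,
    GROUP_VH,
    Atlas,
    MorphometricTable,
    ValidationError,
)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: discrete support of the NPI hallucination subscale (frequency x severity)
NPI_SUPPORT = np.array([0, 1, 2, 3, 4, 6, 8, 9, 12])
# zero-inflated distribution over the support for hallucinating patients;
# the real score distribution is unpublished, this is a documented assumption
_NPI_PROBS_VH = np.array([0.05, 0.14, 0.16, 0.15, 0.14, 0.13, 0.10, 0.07, 0.06])


# ---------------------------------------------------------------------------
# atlas generation
# ---------------------------------------------------------------------------

def generate_atlas(n_per_hemisphere: int, seed: int) -> Atlas:
    """Quasi-uniform symmetric parcellation of the sphere.

    Left-hemisphere centroids are placed on the ``x < 0`` half-sphere by a
    Fibonacci lattice; right-hemisphere centroids are their x-mirrored
    copies, giving the exact mirror pairing the spin test requires. The
    seed rotates the lattice about the x axis.
    """
    if n_per_hemisphere < 2:
        raise ValueError("n_per_hemisphere must be >= 2")
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_per_hemisphere)
    # cos of polar angle from the -x axis, uniform on (0, 1)
    c = (i + 0.5) / n_per_hemisphere
    s = np.sqrt(1.0 - c**2)
    phi = i * _GOLDEN_ANGLE + offset
    left = np.column_stack([-c, s * np.cos(phi), s * np.sin(phi)])
    right = left * np.array([-1.0, 1.0, 1.0])
    centroid = np.vstack([left, right])
    centroid /= np.linalg.norm(centroid, axis=1, keepdims=True)

    labels = tuple(
        f"{h}_{k:03d}" for h in ("L", "R") for k in range(n_per_hemisphere)
    )
    hemisphere = np.array(["L"] * n_per_hemisphere + ["R"] * n_per_hemisphere)
    mirror = np.concatenate([i + n_per_hemisphere, i]).astype(int)
    # coarse lobes by (y, z) quadrant; deterministic, mirror-symmetric
    y, z = centroid[:, 1], centroid[:, 2]
    lobe = np.where(
        z >= 0,
        np.where(y >= 0, "frontal", "parietal"),
        np.where(y >= 0, "temporal", "occipital"),
    )
    return Atlas(
        region_id=labels,
        hemisphere=hemisphere,
        lobe=lobe,
        centroid=centroid,
        mirror_idx=mirror,
    )


def angular_distances(centroids: np.ndarray) -> np.ndarray:
    """Pairwise great-circle angles (radians) between unit vectors."""
    cosines = np.clip(centroids @ centroids.T, -1.0, 1.0)
    return np.arccos(cosines)


def adjacent_pairs(atlas: Atlas, k: int = 1) -> np.ndarray:
    """Index pairs of each region and its k nearest angular neighbours."""
    theta = angular_distances(atlas.centroid)
    np.fill_diagonal(theta, np.inf)
    nbrs = np.argsort(theta, axis=1)[:, :k]
    i = np.repeat(np.arange(atlas.n_regions), k)
    return np.column_stack([i, nbrs.ravel()])


# ---------------------------------------------------------------------------
# cohort ground truth
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Planted generative parameters for a synthetic cohort.

    ``covariate_betas`` apply to standardised covariates (age and TIV
    z-scored by their population moments, gender as a centred female
    indicator), so each beta is in measure units per covariate SD.
    ``loadings`` maps group label -> (regions x factors) matrix; the
    implied residual covariance of a group is
    ``L @ L.T + diag(noise_sd**2)``.
    """

    baseline: np.ndarray
    delta: np.ndarray
    site_shift: dict
    site_scale: dict
    covariate_betas: dict
    loadings: dict
    noise_sd: np.ndarray
    hub_regions: dict = field(default_factory=dict)
    community_labels: np.ndarray | None = None

    def __post_init__(self):
        for site, sc in self.site_scale.items():
            if np.any(np.asarray(sc) <= 0):
                raise ValidationError(f"site_scale must be > 0 (site {site})")
        if np.any(self.noise_sd <= 0):
            raise ValidationError("noise_sd must be > 0")
        for g, L in self.loadings.items():
            L = np.asarray(L, float)
            if not np.all(np.isfinite(L)):
                raise ValidationError(f"non-finite loadings for group {g}")
            implied = L @ L.T + np.diag(self.noise_sd**2)
            w = np.linalg.eigvalsh(implied)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValidationError(
                    f"implied covariance for group {g} is not PSD"
                )

    @property
    def sites(self) -> list:
        return sorted(self.site_shift)

    def total_sd(self, group: str) -> np.ndarray:
        """Residual SD including the latent-factor contribution."""
        L = np.asarray(self.loadings[group], float)
        return np.sqrt(np.sum(L**2, axis=1) + self.noise_sd**2)

    def implied_correlation(self, group: str) -> np.ndarray:
        L = np.asarray(self.loadings[group], float)
        cov = L @ L.T + np.diag(self.noise_sd**2)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def to_json(self, path) -> None:
        enc = lambda x: np.asarray(x).tolist()
        payload = {
            "baseline": enc(self.baseline),
            "delta": enc(self.delta),
            "site_shift": {s: enc(v) for s, v in self.site_shift.items()},
            "site_scale": {s: enc(v) for s, v in self.site_scale.items()},
            "covariate_betas": {
                c: enc(v) for c, v in self.covariate_betas.items()
            },
            "loadings": {g: enc(v) for g, v in self.loadings.items()},
            "noise_sd": enc(self.noise_sd),
            "hub_regions": {g: list(v) for g, v in self.hub_regions.items()},
            "community_labels": enc(self.community_labels)
            if self.community_labels is not None
            else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            d = json.load(fh)
        arr = lambda x: np.asarray(x, float)
        return cls(
            baseline=arr(d["baseline"]),
            delta=arr(d["delta"]),
            site_shift={s: arr(v) for s, v in d["site_shift"].items()},
            site_scale={s: arr(v) for s, v in d["site_scale"].items()},
            covariate_betas={c: arr(v) for c, v in d["covariate_betas"].items()},
            loadings={g: arr(v) for g, v in d["loadings"].items()},
            noise_sd=arr(d["noise_sd"]),
            hub_regions={g: tuple(v) for g, v in d.get("hub_regions", {}).items()},
            community_labels=arr(d["community_labels"]).astype(int)
            if d.get("community_labels") is not None
            else None,
        )


def loadings_from_correlation(
    target_corr: np.ndarray,
    total_sd: np.ndarray,
    noise_share: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Factor loadings realising a target residual correlation matrix.

    Each region's variance ``total_sd**2`` is split into a latent part
    (fraction ``1 - noise_share``) and idiosyncratic noise (fraction
    ``noise_share``); the latent part carries the off-diagonal structure.
    Returns ``(loadings, noise_sd)`` with
    ``loadings @ loadings.T + diag(noise_sd**2)`` matching the target up
    to the per-region scales. Raises when the target is not achievable as
    a positive semidefinite latent covariance.
    """
    target_corr = np.asarray(target_corr, float)
    total_sd = np.asarray(total_sd, float)
    noise_share = np.broadcast_to(np.asarray(noise_share, float), total_sd.shape)
    if not np.allclose(target_corr, target_corr.T, atol=1e-10):
        raise ValidationError("target correlation must be symmetric")
    latent_unit = target_corr.copy()
    np.fill_diagonal(latent_unit, 1.0 - noise_share)
    w, V = np.linalg.eigh(latent_unit)
    if w.min() < -1e-8:
        raise ValidationError(
            "target correlation not achievable as PSD latent covariance"
        )
    L = (V * np.sqrt(np.clip(w, 0.0, None))) * total_sd[:, None]
    noise_sd = np.sqrt(noise_share) * total_sd
    return L, noise_sd


def network_truth(
    atlas: Atlas,
    total_sd: np.ndarray,
    n_communities: int = 4,
    within_r: float = 0.22,
    hub_region: str | None = None,
    hub_r: float = 0.32,
    hub_own_community_r: float = 0.22,
    spoke_within_r: float = 0.12,
    hub_spokes_per_community: int = 1,
    noise_share: float = 0.5,
    hub_noise_share: float = 0.05,
    spoke_noise_share: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    """Community + hub correlation structure as factor loadings.

    Regions split into ``n_communities`` blocks with within-block residual
    correlation ``within_r``. When ``hub_region`` is given it sits inside
    the first community (correlating at ``hub_own_community_r`` with its
    members, hence inheriting that community's degree) and is the sole
    strong bridge to every other community via ``hub_r`` correlations
    with designated spokes — a betweenness hub once the matrix is
    density-thresholded. Spokes couple only weakly
    (``spoke_within_r``) to their own community so the star stays
    positive semidefinite next to the block structure. Returns
    ``(loadings, noise_sd, community_labels, spoke_labels)``.
    """
    rng = np.random.default_rng(seed)
    R = atlas.n_regions
    labels = np.asarray(atlas.region_id)
    comm = np.arange(R) % n_communities
    rng.shuffle(comm)
    target = np.full((R, R), 0.0)
    for c in range(n_communities):
        idx = np.flatnonzero(comm == c)
        target[np.ix_(idx, idx)] = within_r
    np.fill_diagonal(target, 1.0)
    share = np.full(R, noise_share)
    spokes = ()
    if hub_region is not None:
        h = int(np.flatnonzero(labels == hub_region)[0])
        home = int(comm[h])
        own = np.flatnonzero((comm == home) & (np.arange(R) != h))
        target[h, :] = 0.0
        target[:, h] = 0.0
        target[h, own] = hub_own_community_r
        target[own, h] = hub_own_community_r
        target[h, h] = 1.0
        share[h] = hub_noise_share
        spoke_idx = []
        for c in range(n_communities):
            if c == home:
                continue
            idx = np.flatnonzero((comm == c) & (np.arange(R) != h))
            chosen = rng.choice(
                idx, size=min(hub_spokes_per_community, idx.size), replace=False
            )
            spoke_idx.extend(int(j) for j in chosen)
        for sp in spoke_idx:
            idx = np.flatnonzero(comm == comm[sp])
            target[sp, idx] = spoke_within_r
            target[idx, sp] = spoke_within_r
            target[sp, sp] = 1.0
            share[sp] = spoke_noise_share
        target[h, spoke_idx] = hub_r
        target[spoke_idx, h] = hub_r
        spokes = tuple(labels[spoke_idx])
    L, noise_sd = loadings_from_correlation(target, np.asarray(total_sd, float), share)
    return L, noise_sd, comm, spokes


def default_truth(
    atlas: Atlas,
    n_affected: int = 20,
    effect_size: float = 0.3,
    sites: tuple = ("siteA", "siteB", "siteC"),
    site_shift_sd: float = 1.0,
    site_scale_sd: float = 0.2,
    latent: bool = True,
    plant_hub: bool = False,
    seed: int = 0,
) -> CohortTruth:
    """Study-condition ground truth for the default synthetic cohort.

    Plants ``effect_size`` x (total residual SD) cortical thinning in
    ``n_affected`` regions, additive site shifts of ``site_shift_sd``
    noise SDs, multiplicative site scales lognormal around 1, and
    age/gender/TIV covariate effects at thickness-like magnitudes. With
    ``plant_hub`` the hallucinating group receives a group-specific
    betweenness hub; with ``latent=False`` the inter-regional covariance
    is diagonal.
    """
    rng = np.random.default_rng(seed)
    R = atlas.n_regions
    baseline = rng.uniform(2.2, 2.9, size=R)  # mm, thickness-like
    total_sd = rng.uniform(0.2, 0.3, size=R)

    hub = atlas.region_id[int(rng.integers(R))] if plant_hub else None
    if latent:
        L_vh, noise_sd, comm, _ = network_truth(
            atlas, total_sd, hub_region=hub, seed=int(rng.integers(2**31))
        )
        # control group: same noise split, communities without the hub
        novh_target = np.zeros((R, R))
        for c in np.unique(comm[comm >= 0]):
            idx = np.flatnonzero(comm == c)
            novh_target[np.ix_(idx, idx)] = 0.22
        np.fill_diagonal(novh_target, 1.0)
        share = (noise_sd / total_sd) ** 2
        L_novh, _ = loadings_from_correlation(novh_target, total_sd, share)
    else:
        noise_sd = total_sd.copy()
        comm = None
        L_vh = np.zeros((R, 1))
        L_novh = np.zeros((R, 1))

    delta = np.zeros(R)
    affected = rng.choice(R, size=min(n_affected, R), replace=False)
    delta[affected] = -effect_size * total_sd[affected]  # thinning in VH

    site_shift = {s: rng.normal(0.0, site_shift_sd) * noise_sd for s in sites}
    site_scale = {
        s: np.exp(rng.normal(0.0, site_scale_sd)) * np.ones(R) for s in sites
    }
    covariate_betas = {
        "age": -0.35 * noise_sd,
        "gender": 0.10 * noise_sd,
        "tiv": 0.20 * noise_sd,
    }
    return CohortTruth(
        baseline=baseline,
        delta=delta,
        site_shift=site_shift,
        site_scale=site_scale,
        covariate_betas=covariate_betas,
        loadings={GROUP_VH: L_vh, GROUP_NOVH: L_novh},
        noise_sd=noise_sd,
        hub_regions={GROUP_VH: (hub,)} if hub else {},
        community_labels=comm,
    )


def null_truth(atlas: Atlas, seed: int = 0) -> CohortTruth:
    """Truth with no group effect, no site effects, no latent structure."""
    truth = default_truth(atlas, seed=seed, latent=False)
    R = atlas.n_regions
    truth.delta = np.zeros(R)
    truth.site_shift = {s: np.zeros(R) for s in truth.site_shift}
    truth.site_scale = {s: np.ones(R) for s in truth.site_scale}
    truth.covariate_betas = {}
    truth.hub_regions = {}
    return truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 66.0, 8.5, 40.0, 90.0
_TIV_MEAN, _TIV_SD = 1.45e6, 1.5e5
_P_FEMALE = 0.4

#: default plan: 3 sites x 2 groups, 200 subjects in total
DEFAULT_COHORT_PLAN = {
    "siteA": (34, 33),
    "siteB": (33, 33),
    "siteC": (33, 34),
}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    atlas: Atlas,
    truth: CohortTruth,
    n_per_group_per_site: int | dict,
    seed: int,
    measure_kind: str = "thickness",
    missing_updrs3_frac: float = 0.0,
) -> tuple[MorphometricTable, pd.DataFrame]:
    """Draw a multi-site two-group cohort from the planted model.

    ``value(subject, region) = baseline + covariate terms + delta * 1[VH]
    + latent-factor term + site_shift + site_scale * noise``.

    ``n_per_group_per_site`` is either one count used for every
    (site, group) cell or a mapping ``site -> (n_VH, n_noVH)``.
    """
    rng = np.random.default_rng(seed)
    sites = truth.sites
    if len(sites) < 1:
        raise ValueError("truth must declare at least one site")
    if isinstance(n_per_group_per_site, int):
        plan = {s: (n_per_group_per_site, n_per_group_per_site) for s in sites}
    else:
        plan = {s: tuple(n_per_group_per_site[s]) for s in sites}
    for s, (nv, nn) in plan.items():
        if nv < 2 or nn < 2:
            raise ValueError(f"need >= 2 subjects per group per site ({s})")

    rows = []
    values = []
    counter = 0
    for s in sites:
        for group, n in zip((GROUP_VH, GROUP_NOVH), plan[s]):
            age = _truncated_normal(rng, _AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI, n)
            female = rng.random(n) < _P_FEMALE
            tiv = rng.normal(_TIV_MEAN, _TIV_SD, size=n)
            led = np.clip(rng.normal(550.0, 250.0, size=n), 0.0, None)
            mmse = np.clip(np.round(rng.normal(28.0, 1.5, size=n)), 24, 30)
            updrs3 = np.clip(np.round(rng.normal(25.0, 11.0, size=n)), 0, 132)
            onset = np.round(np.clip(rng.normal(5.0, 3.0, size=n), 0.5, 20.0), 1)
            if group == GROUP_VH:
                npi = rng.choice(NPI_SUPPORT, size=n, p=_NPI_PROBS_VH)
            else:
                npi = np.zeros(n)

            z_age = (age - _AGE_MEAN) / _AGE_SD
            z_tiv = (tiv - _TIV_MEAN) / _TIV_SD
            z_gender = female.astype(float) - _P_FEMALE
            zcov = {"age": z_age, "gender": z_gender, "tiv": z_tiv}
            cov_term = np.zeros((n, atlas.n_regions))
            for name, beta in truth.covariate_betas.items():
                cov_term += np.outer(zcov[name], beta)

            L = np.asarray(truth.loadings[group], float)
            factors = rng.standard_normal((n, L.shape[1]))
            latent = factors @ L.T
            eps = rng.standard_normal((n, atlas.n_regions)) * truth.noise_sd
            vals = (
                truth.baseline
                + cov_term
                + (truth.delta if group == GROUP_VH else 0.0)
                + latent
                + truth.site_shift[s]
                + truth.site_scale[s] * eps
            )
            values.append(vals)
            for k in range(n):
                rows.append(
                    {
                        "subject_id": f"sub{counter:04d}",
                        "site": s,
                        "group": group,
                        "age": age[k],
                        "gender": "F" if female[k] else "M",
                        "tiv": tiv[k],
                        "led": led[k],
                        "mmse": mmse[k],
                        "updrs3": updrs3[k],
                        "onset": onset[k],
                        "npi": npi[k],
                    }
                )
                counter += 1
    meta = pd.DataFrame(rows)
    if missing_updrs3_frac > 0:
        n_missing = int(round(missing_updrs3_frac * len(meta)))
        drop = rng.choice(len(meta), size=n_missing, replace=False)
        meta.loc[drop, "updrs3"] = np.nan
    table = MorphometricTable(
        pd.DataFrame(
            np.vstack(values),
            index=pd.Index(meta["subject_id"], name="subject_id"),
            columns=list(atlas.region_id),
        ),
        measure_kind,
    )
    return table, meta


# ---------------------------------------------------------------------------
# receptor-like smooth spatial maps
# ---------------------------------------------------------------------------

def _smooth_field(atlas: Atlas, smoothness_deg: float, rng) -> np.ndarray:
    """Gaussian-kernel mixture of white noise on the parcel centroids."""
    white = rng.standard_normal(atlas.n_regions)
    if smoothness_deg <= 1e-9:
        field_ = white
    else:
        s = np.deg2rad(smoothness_deg)
        theta = angular_distances(atlas.centroid)
        K = np.exp(-0.5 * (theta / s) ** 2)
        field_ = K @ white
    field_ = field_ - field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_receptor_map(
    atlas: Atlas,
    smoothness: float,
    seed: int,
    target: tuple | None = None,
    receptor_label: str = "synthetic",
):
    """Smooth nonnegative binding-potential-like map on the atlas.

    ``target=(values, rho)`` blends the smooth field with a target map
    (e.g. a planted difference map) so the sample Pearson correlation
    with the target equals ``rho`` exactly: the field component
    orthogonal to the target is rescaled in closed form, so no iterative
    re-blending is needed. Returns a
    :class:`cortmorph.receptormap.ReceptorMap`.
    """
    from .receptormap import ReceptorMap  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    y = _smooth_field(atlas, smoothness, rng)
    if target is not None:
        tvals, rho = target
        tvals = np.asarray(tvals, float)
        if abs(rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if tvals.std() == 0:
            raise ValueError("target map has zero variance")
        w = (tvals - tvals.mean()) / tvals.std()
        resid = y - (y @ w / (w @ w)) * w
        rsd = resid.std()
        if rsd == 0 and abs(rho) < 1:
            raise ValueError("smooth field degenerate against target")
        e = resid / rsd if rsd > 0 else resid
        y = rho * w + np.sqrt(max(0.0, 1.0 - rho**2)) * e
    bp = y - y.min() + 0.1  # affine rescale to nonnegative binding values
    series = pd.Series(bp, index=list(atlas.region_id), name="bp")
    return ReceptorMap(bp=series, receptor_label=receptor_label)


def generate_smooth_null_maps(
    atlas: Atlas, smoothness: float, n_maps: int, seed: int
) -> list[np.ndarray]:
    """Independent smooth random fields for spin-test calibration."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    return [_smooth_field(atlas, smoothness, rng) for _ in range(n_maps)]


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def save_cohort(table: MorphometricTable, meta: pd.DataFrame, out_dir) -> None:
    """Write morphometrics + metadata CSVs (empty cell = missing)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"morphometrics_{table.measure_kind}.csv")
    meta.to_csv(out / "metadata.csv", index=False)
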