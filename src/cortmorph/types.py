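"""Core data containers shared across the analysis stages.

The pipeline operates on three kinds of objects: a parcellation
(:class:`Atlas`), per-subject parcellated measurements
(:class:`MorphometricTable`), and per-subject metadata (a plain
:class:`pandas.DataFrame` with the columns in :data:`METADATA_COLUMNS`).
Group labels are ``"VH"`` (patients with visual hallucinations) and
``"noVH"`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical group labels
GROUP_VH = "VH"
GROUP_NOVH = "noVH"

#: metadata columns every cohort carries (empty cell = missing value)
METADATA_COLUMNS = (
    "subject_id",
    "site",
    "group",
    "age",
    "gender",
    "tiv",
    "led",
    "mmse",
    "updrs3",
    "onset",
    "npi",
)

#: columns that must never be missing
METADATA_REQUIRED = ("subject_id", "site", "group")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class Atlas:
    """A symmetric cortical parcellation on the unit sphere.

    Parameters
    ----------
    region_id
        Ordered region labels.
    hemisphere
        ``"L"`` or ``"R"`` per region.
    lobe
        Coarse anatomical grouping per region (frontal / parietal /
        temporal / occipital in the synthetic atlases).
    centroid
        ``(n_regions, 3)`` unit vectors giving each parcel centre on a
        sphere; the spin test rotates these.
    mirror_idx
        Index of the homologous contralateral region, or ``-1`` when no
        mirror is defined.
    """

    region_id: tuple
    hemisphere: np.ndarray
    lobe: np.ndarray
    centroid: np.ndarray
    mirror_idx: np.ndarray

    def __post_init__(self):
        n = len(self.region_id)
        if self.centroid.shape != (n, 3):
            raise ValidationError("centroid must be (n_regions, 3)")
        norms = np.linalg.norm(self.centroid, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("centroids must have unit norm")
        m = self.mirror_idx
        paired = m >= 0
        if np.any(m[m[paired]] != np.flatnonzero(paired)):
            raise ValidationError("mirror pairing must be an involution")

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    @property
    def is_symmetric(self) -> bool:
        """Equal region counts per hemisphere with full mirror pairing."""
        nl = int(np.sum(self.hemisphere == "L"))
        nr = int(np.sum(self.hemisphere == "R"))
        return nl == nr and bool(np.all(self.mirror_idx >= 0))

    def indices(self, hemisphere: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemisphere)

    def to_frame(self) -> pd.DataFrame:
        mirror_of = [
            self.region_id[j] if j >= 0 else "" for j in self.mirror_idx
        ]
        return pd.DataFrame(
            {
                "region_id": list(self.region_id),
                "hemisphere": self.hemisphere,
                "lobe": self.lobe,
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
                "mirror_of": mirror_of,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Atlas":
        df = pd.read_csv(path, keep_default_na=False)
        labels = tuple(df["region_id"])
        pos = {r: i for i, r in enumerate(labels)}
        mirror = np.array(
            [pos[m] if m != "" else -1 for m in df["mirror_of"]], dtype=int
        )
        cent = df[["x", "y", "z"]].to_numpy(float)
        # re-normalise: CSV round-trips lose a few ulps
        cent = cent / np.linalg.norm(cent, axis=1, keepdims=True)
        return cls(
            region_id=labels,
            hemisphere=df["hemisphere"].to_numpy(),
            lobe=df["lobe"].to_numpy(),
            centroid=cent,
            mirror_idx=mirror,
        )


@dataclass
class MorphometricTable:
    """Subjects x regions measurements for one morphometric kind.

    ``values`` is indexed by subject_id with one column per region; units
    are mm (thickness), mm^2 (surface area) or mm^3 (volume).
    """

    values: pd.DataFrame
    measure_kind: str = "thickness"

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()]
            raise ValidationError(f"duplicate subject_ids: {list(dupes[:5])}")
        arr = self.values.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("morphometric values must be finite")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def regions(self) -> pd.Index:
        return self.values.columns

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(float)

    def copy_with(self, array: np.ndarray) -> "MorphometricTable":
        return MorphometricTable(
            pd.DataFrame(
                array, index=self.values.index, columns=self.values.columns
            ),
            self.measure_kind,
        )

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, measure_kind: str = "thickness") -> "MorphometricTable":
        df = pd.read_csv(path).set_index("subject_id")
        return cls(df, measure_kind)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check metadata structure and score ranges; returns the frame."""
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    for col in METADATA_REQUIRED:
        if meta[col].isna().any():
            raise ValidationError(f"metadata column {col!r} has missing entries")
    if meta["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject_ids in metadata")
    bad = set(meta["group"]) - {GROUP_VH, GROUP_NOVH}
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    ranges = {"mmse": (0, 30), "updrs3": (0, 132), "npi": (0, 12)}
    for col, (lo, hi) in ranges.items():
        if col in meta.columns:
            v = pd.to_numeric(meta[col], errors="coerce")
            obs = v.dropna()
            if ((obs < lo) | (obs > hi)).any():
                raise ValidationError(f"{col} outside [{lo}, {hi}]")
    return meta


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path))


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_receptor_map(path) -> pd.Series:
    """Receptor binding-potential CSV (region_id, bp) -> Series."""
    df = pd.read_csv(path)
    return pd.Series(df["bp"].to_numpy(float), index=df["region_id"], name="bp")


def write_receptor_map(bp: pd.Series, path) -> None:
    pd.DataFrame({"region_id": bp.index, "bp": bp.to_numpy()}).to_csv(
        path, index=False
    )
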