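"""Correlation-matrix PCA of the group-different regions.

Reduces the flagged regions to latent dimensions (a frontal and an
occipital dimension in the study this pipeline reproduces). Variables
(regions) are standardized, so eigenvalues sum to the number of regions
and the Kaiser rule (eigenvalue > 1) selects the retained dimensions.
Contributions and squared cosines follow the usual multivariate
conventions: for region i on component k with eigenvector entry v_ik and
loading l_ik = v_ik * sqrt(lambda_k), contribution = 100 * v_ik^2 and
cos^2 = l_ik^2 (summing to 1 over all components).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MorphometricTable, ValidationError


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    loadings: pd.DataFrame       # regions x components
    contributions: pd.DataFrame  # % per region per component
    cos2: pd.DataFrame           # squared cosine per region per component
    n_components_retained: int   # Kaiser rule at construction time

    @property
    def regions(self) -> list:
        return list(self.loadings.index)


def run_pca(data) -> PCAResult:
    """PCA of the region-by-region correlation matrix.

    ``data`` is subjects x regions (DataFrame or MorphometricTable).
    Sign convention: the largest-|loading| entry of each component is
    made positive, so loadings are reproducible across implementations.
    """
    if isinstance(data, MorphometricTable):
        data = data.values
    X = data.to_numpy(float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    regions = (
        list(data.columns) if isinstance(data, pd.DataFrame)
        else [f"var{i}" for i in range(X.shape[1])]
    )
    n, m = X.shape
    if m < 2 or n < 3:
        raise ValidationError("need >= 2 regions and >= 3 subjects")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [regions[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant regions: {bad}")
    corr = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(m):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    loadings = V * np.sqrt(w)
    comps = [f"PC{k + 1}" for k in range(m)]
    contrib = 100.0 * V**2
    cos2 = loadings**2
    retained = int(np.sum(w > 1.0))
    return PCAResult(
        eigenvalues=w,
        variance_fraction=w / w.sum(),
        loadings=pd.DataFrame(loadings, index=regions, columns=comps),
        contributions=pd.DataFrame(contrib, index=regions, columns=comps),
        cos2=pd.DataFrame(cos2, index=regions, columns=comps),
        n_components_retained=retained,
    )


def select_components(
    res: PCAResult, criterion: str = "kaiser", top: int = 5
) -> dict:
    """Retained dimensions with their top contributing regions.

    ``criterion="kaiser"`` keeps eigenvalues > 1 (at least one component
    is always kept). Per retained dimension regions are ranked both by
    contribution and by squared cosine; scree data is included for
    reporting.
    """
    if criterion != "kaiser":
        raise ValueError("only the Kaiser (eigenvalue > 1) rule is implemented")
    k = max(1, int(np.sum(res.eigenvalues > 1.0)))
    dims = []
    for j in range(k):
        col = f"PC{j + 1}"
        by_contrib = res.contributions[col].sort_values(ascending=False)
        by_cos2 = res.cos2[col].sort_values(ascending=False)
        dims.append(
            {
                "component": col,
                "eigenvalue": float(res.eigenvalues[j]),
                "variance_pct": float(100.0 * res.variance_fraction[j]),
                "top_contributors": list(by_contrib.index[:top]),
                "top_cos2": list(by_cos2.index[:top]),
            }
        )
    return {
        "n_retained": k,
        "dimensions": dims,
        "scree": {
            "eigenvalues": res.eigenvalues.tolist(),
            "variance_pct": (100.0 * res.variance_fraction).tolist(),
        },
    }


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> float:
    """Mean Tucker congruence between matched columns of two loading sets."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    k = min(A.shape[1], B.shape[1])
    # greedy column matching on |congruence|
    used = set()
    vals = []
    for i in range(k):
        best, best_j = 0.0, None
        for j in range(B.shape[1]):
            if j in used:
                continue
            c = abs(
                A[:, i] @ B[:, j]
                / (np.linalg.norm(A[:, i]) * np.linalg.norm(B[:, j]))
            )
            if c > best:
                best, best_j = c, j
        used.add(best_j)
        vals.append(best)
    return float(np.mean(vals))
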