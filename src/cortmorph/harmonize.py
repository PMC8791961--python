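"""Empirical-Bayes location-scale harmonisation of multi-site tables.

Implements the parametric ComBat model for parcellated morphometry:

    y_{sjr} = alpha_r + x_j' beta_r + gamma_{sr} + delta_{sr} eps_{sjr}

where ``s`` indexes site/scanner, ``j`` subject and ``r`` region. Site
location effects ``gamma`` get a normal prior and scale effects
``delta^2`` an inverse-gamma prior, with hyperparameters estimated per
site by method of moments and posterior means iterated to convergence.
Declared biological covariates (by default the group contrast plus age,
gender and head size) are protected: their fitted contribution is
removed before the site effects are estimated and restored afterwards.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import MorphometricTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("group", "age", "gender", "tiv")


class SingularDesignError(ValidationError):
    """Design matrix is rank deficient; names the collinear columns."""


def design_matrix(
    meta: pd.DataFrame, covariates, add_intercept: bool = True
) -> pd.DataFrame:
    """Numeric design from metadata columns; categoricals are dummy-coded."""
    cols = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(meta))
    for name in covariates:
        if name not in meta.columns:
            raise ValidationError(f"covariate {name!r} not in metadata")
        col = meta[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:  # first level is the reference
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
        else:
            vals = pd.to_numeric(col)
            if vals.isna().any():
                raise ValidationError(f"covariate {name!r} has missing values")
            cols[name] = vals.to_numpy(float)
    X = pd.DataFrame(cols, index=meta.index)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = np.empty((arr.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([kept, arr[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise SingularDesignError(
            f"design matrix rank deficient; collinear columns: {bad}"
        )


@dataclass
class HarmonisationFit:
    """Fitted ComBat model, sufficient to adjust any table from seen sites."""

    regions: list
    sites: list
    covariate_names: list
    alpha: np.ndarray           # grand mean per region
    beta: np.ndarray            # (n_covariate_cols, regions)
    sigma: np.ndarray           # pooled residual SD per region
    gamma_star: pd.DataFrame    # EB-shrunken additive site effects (std units)
    delta_star: pd.DataFrame    # EB-shrunken multiplicative site effects
    gamma_hat: pd.DataFrame     # raw standardized site location effects
    delta_hat: pd.DataFrame     # raw standardized site scale effects (SD)
    hyper: dict                 # per-site prior parameters
    n_iter: dict                # per-site iterations to convergence
    converged: dict
    empirical_bayes: bool
    measure_kind: str

    def to_json(self, path) -> None:
        payload = {
            "regions": list(self.regions),
            "sites": list(self.sites),
            "covariate_names": list(self.covariate_names),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.to_dict(orient="index"),
            "delta_star": self.delta_star.to_dict(orient="index"),
            "hyper": {s: {k: float(v) for k, v in h.items()} for s, h in self.hyper.items()},
            "n_iter": self.n_iter,
            "converged": self.converged,
            "empirical_bayes": self.empirical_bayes,
            "measure_kind": self.measure_kind,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def fit_combat(
    table: MorphometricTable,
    meta: pd.DataFrame,
    biological_covariates=DEFAULT_COVARIATES,
    empirical_bayes: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> HarmonisationFit:
    """Estimate site effects with the declared covariates protected.

    Requires at least two sites with >= 3 subjects each. Raises
    :class:`SingularDesignError` naming collinear columns when the
    combined site + covariate design is rank deficient.
    """
    meta = meta.set_index("subject_id").loc[table.subjects].reset_index()
    sites = sorted(pd.unique(meta["site"]))
    if len(sites) < 2:
        raise ValidationError("harmonisation needs >= 2 sites")
    counts = meta["site"].value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValidationError(f"sites with < 3 subjects: {list(small.index)}")

    Y = table.to_numpy()
    n, R = Y.shape
    # site indicator block (one column per site, no global intercept)
    S = np.column_stack([(meta["site"] == s).to_numpy(float) for s in sites])
    Xbio = design_matrix(meta, biological_covariates, add_intercept=False)
    full = pd.concat(
        [pd.DataFrame(S, columns=[f"site[{s}]" for s in sites], index=meta.index), Xbio],
        axis=1,
    )
    _check_full_rank(full)
    D = full.to_numpy(float)

    B, *_ = np.linalg.lstsq(D, Y, rcond=None)
    n_sites = len(sites)
    site_intercepts = B[:n_sites]          # (sites, regions)
    beta = B[n_sites:]                     # (covariate cols, regions)
    w = counts.loc[sites].to_numpy(float) / n
    alpha = w @ site_intercepts            # weighted grand mean -> identifiable

    fitted = D @ B
    sigma2 = np.mean((Y - fitted) ** 2, axis=0)
    if np.any(sigma2 <= 0):
        bad = [table.regions[i] for i in np.flatnonzero(sigma2 <= 0)]
        raise ValidationError(f"zero residual variance in regions: {bad}")
    sigma = np.sqrt(sigma2)

    stand_mean = alpha + Xbio.to_numpy(float) @ beta
    Z = (Y - stand_mean) / sigma

    gamma_hat = np.empty((n_sites, R))
    delta2_hat = np.empty((n_sites, R))
    gamma_star = np.empty((n_sites, R))
    delta2_star = np.empty((n_sites, R))
    hyper, n_iter, converged = {}, {}, {}
    for si, s in enumerate(sites):
        idx = (meta["site"] == s).to_numpy()
        Zs = Z[idx]
        ns = Zs.shape[0]
        g_hat = Zs.mean(axis=0)
        d2_hat = Zs.var(axis=0, ddof=1)
        gamma_hat[si] = g_hat
        delta2_hat[si] = d2_hat
        if not empirical_bayes:
            gamma_star[si] = g_hat
            delta2_star[si] = d2_hat
            hyper[s] = {}
            n_iter[s] = 0
            converged[s] = True
            continue
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        m, v = d2_hat.mean(), d2_hat.var(ddof=1)
        # inverse-gamma prior by method of moments
        lam = (2.0 * v + m**2) / v
        theta = (m * v + m**3) / v
        hyper[s] = {
            "gamma_bar": g_bar, "tau2": t2, "lambda": lam, "theta": theta
        }
        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        it = 0
        while it < max_iter:
            g_new = (ns * t2 * g_hat + d2_star * g_bar) / (ns * t2 + d2_star)
            ss = np.sum((Zs - g_new) ** 2, axis=0)
            d2_new = (theta + 0.5 * ss) / (ns / 2.0 + lam - 1.0)
            change = max(
                np.max(np.abs(g_new - g_star)), np.max(np.abs(d2_new - d2_star))
            )
            g_star, d2_star = g_new, d2_new
            it += 1
            if change < tol:
                break
        gamma_star[si] = g_star
        delta2_star[si] = d2_star
        n_iter[s] = it
        converged[s] = it < max_iter or change < tol
        if not converged[s]:
            warnings.warn(f"EB posterior iteration did not converge for {s}")

    regions = list(table.regions)
    return HarmonisationFit(
        regions=regions,
        sites=sites,
        covariate_names=list(Xbio.columns),
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        gamma_star=pd.DataFrame(gamma_star, index=sites, columns=regions),
        delta_star=pd.DataFrame(np.sqrt(delta2_star), index=sites, columns=regions),
        gamma_hat=pd.DataFrame(gamma_hat, index=sites, columns=regions),
        delta_hat=pd.DataFrame(np.sqrt(delta2_hat), index=sites, columns=regions),
        hyper=hyper,
        n_iter=n_iter,
        converged=converged,
        empirical_bayes=empirical_bayes,
        measure_kind=table.measure_kind,
    )


def apply_combat(
    fit: HarmonisationFit, table: MorphometricTable, meta: pd.DataFrame
) -> MorphometricTable:
    """Adjust a table using a fitted model; sites must have been seen."""
    meta = meta.set_index("subject_id").loc[table.subjects].reset_index()
    unseen = set(pd.unique(meta["site"])) - set(fit.sites)
    if unseen:
        raise ValidationError(f"sites not present in fit: {sorted(unseen)}")
    if list(table.regions) != list(fit.regions):
        raise ValidationError("region set differs from the fitted table")

    Xbio = design_matrix(
        meta, _covariates_from_columns(fit.covariate_names), add_intercept=False
    )
    if list(Xbio.columns) != list(fit.covariate_names):
        raise ValidationError(
            f"covariate columns {list(Xbio.columns)} do not match fit "
            f"{list(fit.covariate_names)}"
        )
    Y = table.to_numpy()
    stand_mean = fit.alpha + Xbio.to_numpy(float) @ fit.beta
    Z = (Y - stand_mean) / fit.sigma
    gamma = fit.gamma_star.loc[meta["site"]].to_numpy()
    delta = fit.delta_star.loc[meta["site"]].to_numpy()
    adjusted = fit.sigma * (Z - gamma) / delta + stand_mean
    return table.copy_with(adjusted)


def _covariates_from_columns(columns) -> list:
    """Recover original covariate names from dummy-coded column names."""
    names = []
    for c in columns:
        base = c.split("[")[0]
        if base not in names:
            names.append(base)
    return names


def harmonize(
    table: MorphometricTable,
    meta: pd.DataFrame,
    biological_covariates=DEFAULT_COVARIATES,
    **kwargs,
) -> tuple[MorphometricTable, HarmonisationFit]:
    """Fit-and-apply convenience wrapper."""
    fit = fit_combat(table, meta, biological_covariates, **kwargs)
    return apply_combat(fit, table, meta), fit


def site_effect_report(
    table: MorphometricTable,
    meta: pd.DataFrame,
    covariates=(),
) -> pd.DataFrame:
    """Per-region one-way ANOVA on site: F, p and eta^2.

    With ``covariates`` the values are first residualised on them, mirroring
    the harmonisation audit plots. eta^2 = SS_site / SS_total quantifies
    the between-site variance fraction.
    """
    meta = meta.set_index("subject_id").loc[table.subjects].reset_index()
    sites = sorted(pd.unique(meta["site"]))
    if len(sites) < 2:
        raise ValidationError("site report needs >= 2 sites")
    Y = table.to_numpy()
    if covariates:
        X = design_matrix(meta, covariates, add_intercept=True).to_numpy(float)
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y = Y - X @ B + Y.mean(axis=0)
    n, R = Y.shape
    grand = Y.mean(axis=0)
    ss_total = np.sum((Y - grand) ** 2, axis=0)
    ss_between = np.zeros(R)
    for s in sites:
        idx = (meta["site"] == s).to_numpy()
        ns = idx.sum()
        ss_between += ns * (Y[idx].mean(axis=0) - grand) ** 2
    ss_within = ss_total - ss_between
    df_b = len(sites) - 1
    df_w = n - len(sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
        eta2 = np.where(ss_total > 0, ss_between / ss_total, np.nan)
    p = stats.f.sf(F, df_b, df_w)
    return pd.DataFrame(
        {"region_id": list(table.regions), "F": F, "p": p, "eta2": eta2}
    )
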