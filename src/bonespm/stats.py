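"""Group statistics: covariate-adjusted group differences, partial Spearman
correlations, Fisher-Z comparison of correlations, Benjamini-Hochberg FDR,
and the voxel-/vertex-wise statistical parametric maps built from them.

Partial Spearman correlation: rank-transform both variables (average ranks
on ties), residualize each on the covariates by least squares, and take the
Pearson correlation of the residuals; p from a t statistic with
df = n - 2 - n_covariates. Fisher-Z comparison between independent groups
uses z = (atanh r1 - atanh r2) / sqrt(1/(n1-3-k) + 1/(n2-3-k)); subtracting
the covariate count k from the usual n-3 is the standard adjustment for
partial correlations (set ``covariate_df_correction=False`` for plain n-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class CollinearDesignError(ValueError):
    pass


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or np.size(covariates) == 0:
        return np.ones((n, 1))
    C = np.asarray(covariates, np.float64)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _check_collinear(X: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if names is None:
            names = [f"column {j}" for j in range(X.shape[1])]
        raise CollinearDesignError(
            f"collinear design matrix (rank {rank} < {X.shape[1]}): {names}"
        )


def adjusted_group_difference(
    y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """OLS of y on a group indicator plus covariates.

    Returns the group coefficient (second-level mean minus first-level mean,
    adjusted) and its two-sided p from a t distribution with n - p df.
    """
    y = np.asarray(y, np.float64)
    n = len(y)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    ind = (g == levels[1]).astype(np.float64)
    X = np.column_stack([_design(covariates, n), ind])
    if n <= X.shape[1]:
        raise ValueError("too few subjects for the design")
    _check_collinear(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    coef = beta[-1]
    if se == 0:
        return float(coef), 0.0 if coef != 0 else 1.0
    t = coef / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(coef), float(p)


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, axis=0)


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman's rank partial correlation of x and y given covariates."""
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        k = 0
    else:
        C = np.asarray(covariates)
        k = 1 if C.ndim == 1 else C.shape[1]
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return np.nan, np.nan  # constant after ranking: undefined, not a crash
    X = _design(covariates, n)
    _check_collinear(X)
    H = X @ np.linalg.pinv(X)
    ex = rx - H @ rx
    ey = ry - H @ ry
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        return np.nan, np.nan
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        return rho, np.nan
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2 * sps.t.sf(abs(t), df)
    return rho, float(p)


def fisher_z_compare(
    rho1: float,
    n1: int,
    rho2: float,
    n2: int,
    n_covariates: int = 0,
    covariate_df_correction: bool = True,
) -> tuple[float, float]:
    """Compare two independent correlation coefficients via Fisher's Z."""
    if abs(rho1) >= 1 or abs(rho2) >= 1:
        raise ValueError("|rho| = 1 has an infinite Fisher transform")
    k = n_covariates if covariate_df_correction else 0
    d1 = n1 - 3 - k
    d2 = n2 - 3 - k
    if d1 <= 0 or d2 <= 0:
        raise ValueError("group too small for the Fisher-Z comparison")
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / np.sqrt(1.0 / d1 + 1.0 / d2)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: flag all p <= p_(i*) where i* is the
    largest i with p_(i) <= i q / m. NaNs are never flagged and do not
    count toward m."""
    p = np.asarray(p_values, np.float64)
    flags = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return flags
    order = np.argsort(pv)
    sorted_p = pv[order]
    crit = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(sorted_p <= crit)[0]
    if passing.size == 0:
        return flags
    thresh = sorted_p[passing[-1]]
    out = np.zeros(m, dtype=bool)
    out[pv <= thresh] = True
    flags[valid] = out
    return flags


# --------------------------------------------------------------------------
# statistical parametric maps
# --------------------------------------------------------------------------


@dataclass
class StatMap:
    """Per-location statistics in template space (voxels or vertices).

    ``rho``/``p``/``significant`` for a within-group correlation map;
    ``delta_rho``/``z`` additionally for a group comparison (fracture minus
    control). ``n_effective`` is the per-location subject count used.
    """

    rho: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    n_effective: np.ndarray
    n_covariates: int
    delta_rho: np.ndarray | None = None
    z: np.ndarray | None = None


def _residual_maker(X: np.ndarray) -> np.ndarray:
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def correlation_map(
    maps_x: np.ndarray,
    maps_y: np.ndarray,
    covariates: np.ndarray | None,
    q: float = 0.05,
    min_fraction: float = 0.9,
) -> StatMap:
    """Location-wise partial Spearman correlation across subjects.

    ``maps_x``/``maps_y``: (n_subjects, n_locations) with NaN = undefined.
    Locations defined in fewer than ``min_fraction`` of subjects are
    excluded (NaN everywhere, and not counted in the FDR family m).
    """
    X = np.asarray(maps_x, np.float64)
    Y = np.asarray(maps_y, np.float64)
    if X.shape != Y.shape:
        raise ValueError("map stacks must share shape")
    n, n_loc = X.shape
    D = _design(covariates, n)
    k = D.shape[1] - 1
    valid = ~np.isnan(X) & ~np.isnan(Y)
    n_eff = valid.sum(axis=0)
    usable = n_eff >= max(int(np.ceil(min_fraction * n)), k + 4)
    if not usable.any():
        raise ValueError("no location passes the minimum-subject rule")

    rho = np.full(n_loc, np.nan)
    p = np.full(n_loc, np.nan)

    full = usable & (n_eff == n)
    if full.any():
        # vectorized fast path: one residual-maker for all complete locations
        M = _residual_maker(D)
        rx = sps.rankdata(X[:, full], axis=0)
        ry = sps.rankdata(Y[:, full], axis=0)
        ex = M @ rx
        ey = M @ ry
        num = np.einsum("ij,ij->j", ex, ey)
        den = np.sqrt(
            np.einsum("ij,ij->j", ex, ex) * np.einsum("ij,ij->j", ey, ey)
        )
        ok = den > 0
        r = np.full(num.shape, np.nan)
        r[ok] = np.clip(num[ok] / den[ok], -1.0, 1.0)
        df = n - 2 - k
        t = np.full(r.shape, np.nan)
        in_open = ok & (np.abs(r) < 1)
        t[in_open] = r[in_open] * np.sqrt(df / (1.0 - r[in_open] ** 2))
        pv = np.full(r.shape, np.nan)
        pv[in_open] = 2 * sps.t.sf(np.abs(t[in_open]), df)
        pv[ok & ~in_open] = 0.0
        rho[full] = r
        p[full] = pv

    partial_locs = np.nonzero(usable & (n_eff < n))[0]
    for j in partial_locs:
        mask = valid[:, j]
        cov_j = None if covariates is None else np.asarray(covariates)[mask]
        rho[j], p[j] = partial_spearman(X[mask, j], Y[mask, j], cov_j)

    significant = fdr_correct(p, q=q)
    return StatMap(
        rho=rho,
        p=p,
        significant=significant,
        n_effective=n_eff,
        n_covariates=k,
    )


def correlation_difference_map(
    map_control: StatMap,
    map_fracture: StatMap,
    q: float = 0.05,
    covariate_df_correction: bool = True,
) -> StatMap:
    """Fisher-Z comparison of two group correlation maps per location.

    delta_rho is fracture minus control. FDR over the locations defined in
    both groups.
    """
    if map_control.rho.shape != map_fracture.rho.shape:
        raise ValueError("mismatched statistical map domains")
    k = map_control.n_covariates
    kk = k if covariate_df_correction else 0
    r1 = map_fracture.rho
    r2 = map_control.rho
    d1 = map_fracture.n_effective - 3 - kk
    d2 = map_control.n_effective - 3 - kk
    ok = (
        ~np.isnan(r1) & ~np.isnan(r2)
        & (np.abs(r1) < 1) & (np.abs(r2) < 1)
        & (d1 > 0) & (d2 > 0)
    )
    z = np.full(r1.shape, np.nan)
    p = np.full(r1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z[ok] = (np.arctanh(r1[ok]) - np.arctanh(r2[ok])) / np.sqrt(
            1.0 / d1[ok] + 1.0 / d2[ok]
        )
    p[ok] = 2 * sps.norm.sf(np.abs(z[ok]))
    significant = fdr_correct(p, q=q)
    return StatMap(
        rho=r2,
        p=p,
        significant=significant,
        n_effective=np.minimum(map_control.n_effective, map_fracture.n_effective),
        n_covariates=k,
        delta_rho=r1 - r2,
        z=z,
    )
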