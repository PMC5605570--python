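"""Outlier screening and repeated-measures inference.

Measurements from the two (or three) regions of the same animal are
correlated, so treatment effects are estimated with generalized estimating
equations (GEE): a marginal Gaussian identity-link model with a working
within-animal correlation (exchangeable by default, independence available)
and the robust sandwich covariance, which is consistent even when the
working structure is wrong.  Effects are tested with Wald chi-square
statistics on the robust covariance; pairwise cell contrasts use unadjusted
(least-significant-difference) Wald z tests.  Before modeling, values are
screened per treatment x region cell with the interquartile-range rule using
fences at ``Q1 - 2.2 IQR`` and ``Q3 + 2.2 IQR``, a conservative multiplier
that flags only gross outliers.

The estimating-equation iteration alternates (1) weighted least squares for
the coefficients given the working correlation with (2) moment re-estimation
of the correlation parameter and dispersion from Pearson residuals, until
the coefficient step falls below 1e-8 (at most 100 iterations).  Unbalanced
clusters are handled by simply using each cluster's own size; with
independence working correlation the estimate coincides with ordinary least
squares on the stacked data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps

__all__ = ["GeeFit", "iqr_outliers", "outlier_screen", "gee_fit",
           "wald_test", "lsd_posthoc", "covariate_r2", "AliasingError"]


class AliasingError(ValueError):
    """The design matrix is rank deficient."""


class ContrastError(ValueError):
    """A Wald contrast matrix is degenerate."""


# ---------------------------------------------------------------------------
# outlier screening

def iqr_outliers(values, multiplier: float = 2.2) -> np.ndarray:
    """Boolean flags for values outside the Q1/Q3 +- multiplier*IQR fences.

    Quartiles use linear interpolation (the type-7 convention).  With an
    IQR of zero only values differing from the common quartile are flagged.
    NaNs are ignored (never flagged).
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("need at least 4 values for the IQR rule")
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    flags = np.zeros(x.shape, dtype=bool)
    flags[finite] = ((x[finite] < q1 - multiplier * iqr)
                     | (x[finite] > q3 + multiplier * iqr))
    return flags


def outlier_screen(data: pd.DataFrame, value: str, by: list[str],
                   multiplier: float = 2.2) -> tuple[pd.DataFrame,
                                                     pd.DataFrame]:
    """Flag outliers per cell and return (clean data, audit trail).

    Cells smaller than four observations are left unscreened.  The audit
    table lists every excluded row with its cell and fence values.
    """
    keep = np.ones(len(data), dtype=bool)
    audit_rows = []
    for cell, grp in data.groupby(by, sort=False):
        vals = grp[value].to_numpy(dtype=float)
        if np.isfinite(vals).sum() < 4:
            continue
        flags = iqr_outliers(vals, multiplier)
        for pos, flagged in zip(grp.index, flags):
            if flagged:
                keep[data.index.get_loc(pos)] = False
                audit_rows.append({"row": pos, "cell": cell,
                                   "value": data.at[pos, value]})
    return data[keep], pd.DataFrame(audit_rows)


# ---------------------------------------------------------------------------
# GEE

@dataclass
class GeeFit:
    """A fitted Gaussian GEE with robust covariance and Wald test table."""

    params: pd.Series
    robust_cov: pd.DataFrame
    naive_cov: pd.DataFrame
    alpha: float
    scale: float
    cov_struct: str
    n_clusters: int
    n_obs: int
    n_iter: int
    converged: bool
    wald_table: pd.DataFrame
    design_info: object = field(repr=False, default=None)

    @property
    def exog_names(self) -> list[str]:
        return list(self.params.index)


def _exchangeable_rinv(n: int, alpha: float) -> np.ndarray:
    # closed-form inverse of (1-a)I + aJ
    denom = (1.0 - alpha) * (1.0 + (n - 1) * alpha)
    return (np.eye(n) / (1.0 - alpha)
            - (alpha / denom) * np.ones((n, n)))


def gee_fit(data: pd.DataFrame, formula: str, groups: str,
            cov_struct: str = "exchangeable", maxiter: int = 100,
            tol: float = 1e-8) -> GeeFit:
    """Fit ``formula`` by Gaussian identity-link GEE clustered on ``groups``.

    Rows with missing response or covariates are dropped per cluster.  The
    exchangeable correlation parameter is the moment estimator from
    within-cluster products of Pearson residuals; clusters of size one
    contribute nothing to it, and a design with only singleton clusters
    yields alpha = 0 and the ordinary least-squares fit.
    """
    if cov_struct not in ("exchangeable", "independence"):
        raise ValueError("cov_struct must be 'exchangeable' or 'independence'")
    y_mat, x_mat = patsy.dmatrices(formula, data, return_type="dataframe",
                                   NA_action="drop")
    names = list(x_mat.columns)
    X = x_mat.to_numpy(dtype=float)
    y = y_mat.to_numpy(dtype=float).ravel()
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise AliasingError("design matrix is rank deficient; drop aliased "
                            "terms from the formula")
    cluster_ids = data.loc[x_mat.index, groups].to_numpy()
    order = np.argsort(cluster_ids, kind="stable")
    X, y, cluster_ids = X[order], y[order], cluster_ids[order]
    _, starts = np.unique(cluster_ids, return_index=True)
    bounds = np.append(np.sort(starts), len(y))
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    n_clusters = len(slices)
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha = 0.0
    scale = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        resid = y - X @ beta
        scale = float(resid @ resid) / max(len(y) - p, 1)
        if cov_struct == "exchangeable":
            num, pairs = 0.0, 0
            for sl in slices:
                e = resid[sl]
                n_i = e.size
                if n_i > 1:
                    num += ((e.sum() ** 2 - (e ** 2).sum()) / 2.0)
                    pairs += n_i * (n_i - 1) // 2
            if pairs > 0:
                alpha = num / scale / max(pairs - p, 1)
                max_n = max(sl.stop - sl.start for sl in slices)
                alpha = float(np.clip(alpha, -1.0 / (max_n - 1) + 1e-6,
                                      0.999))
            else:
                alpha = 0.0
        bread = np.zeros((p, p))
        rhs = np.zeros(p)
        for sl in slices:
            Xi, yi = X[sl], y[sl]
            n_i = yi.size
            if cov_struct == "exchangeable" and n_i > 1:
                rinv = _exchangeable_rinv(n_i, alpha)
                XtR = Xi.T @ rinv
            else:
                XtR = Xi.T
            bread += XtR @ Xi
            rhs += XtR @ yi
        new_beta = np.linalg.solve(bread, rhs)
        step = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if step < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GEE did not converge in {maxiter} iterations "
                      f"(last step {step:.2e})", stacklevel=2)

    resid = y - X @ beta
    scale = float(resid @ resid) / max(len(y) - p, 1)
    bread = np.zeros((p, p))
    meat = np.zeros((p, p))
    for sl in slices:
        Xi, ei = X[sl], resid[sl]
        n_i = ei.size
        if cov_struct == "exchangeable" and n_i > 1:
            vinv = _exchangeable_rinv(n_i, alpha) / scale
        else:
            vinv = np.eye(n_i) / scale
        XtV = Xi.T @ vinv
        bread += XtV @ Xi
        u = XtV @ ei
        meat += np.outer(u, u)
    bread_inv = np.linalg.inv(bread)
    robust = bread_inv @ meat @ bread_inv
    robust = (robust + robust.T) / 2.0

    fit = GeeFit(
        params=pd.Series(beta, index=names),
        robust_cov=pd.DataFrame(robust, index=names, columns=names),
        naive_cov=pd.DataFrame(bread_inv, index=names, columns=names),
        alpha=alpha if cov_struct == "exchangeable" else 0.0,
        scale=scale, cov_struct=cov_struct, n_clusters=n_clusters,
        n_obs=len(y), n_iter=n_iter, converged=converged,
        wald_table=pd.DataFrame(),
        design_info=x_mat.design_info)
    fit.wald_table = _term_wald_table(fit)
    return fit


def _term_wald_table(fit: GeeFit) -> pd.DataFrame:
    """Omnibus Wald chi-square for every non-intercept model term."""
    rows = []
    di = fit.design_info
    p = len(fit.params)
    for term, sl in zip(di.term_names, di.term_slices.values()):
        if term == "Intercept":
            continue
        L = np.zeros((sl.stop - sl.start, p))
        L[np.arange(sl.stop - sl.start), np.arange(sl.start, sl.stop)] = 1.0
        chi2, df, pval = wald_test(fit, L)
        rows.append({"effect": term, "chi2": chi2, "df": df, "p": pval})
    return pd.DataFrame(rows)


def wald_test(fit: GeeFit, L) -> tuple[float, int, float]:
    """Wald chi-square test of ``L beta = 0`` on the robust covariance.

    Returns ``(chi2, df, p)`` with ``df = rank(L)``.  A singular middle
    matrix falls back to the Moore-Penrose inverse with a warning.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != len(fit.params):
        raise ContrastError(f"contrast has {L.shape[1]} columns, model has "
                            f"{len(fit.params)} coefficients")
    if np.any(np.all(L == 0, axis=1)):
        raise ContrastError("contrast matrix contains an all-zero row")
    df = int(np.linalg.matrix_rank(L))
    if df < L.shape[0]:
        raise ContrastError("contrast rows are linearly dependent")
    lb = L @ fit.params.to_numpy()
    mid = L @ fit.robust_cov.to_numpy() @ L.T
    try:
        sol = np.linalg.solve(mid, lb)
    except np.linalg.LinAlgError:
        warnings.warn("singular contrast covariance; using pseudo-inverse",
                      stacklevel=2)
        sol = np.linalg.pinv(mid) @ lb
    chi2 = float(lb @ sol)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def lsd_posthoc(fit: GeeFit, cells: pd.DataFrame) -> pd.DataFrame:
    """All pairwise cell-mean comparisons by unadjusted Wald z tests.

    ``cells`` holds one row per factorial cell with the model's covariate
    columns (e.g. treatment and region); cell means are predictions at those
    covariate values.  Least-significant-difference testing applies no
    multiplicity adjustment beyond the omnibus gate.
    """
    if fit.design_info is None:
        raise ValueError("fit carries no design information")
    (xc,) = patsy.build_design_matrices([fit.design_info], cells)
    Xc = np.asarray(xc, dtype=float)
    beta = fit.params.to_numpy()
    V = fit.robust_cov.to_numpy()
    means = Xc @ beta
    labels = [" / ".join(str(v) for v in row)
              for row in cells.itertuples(index=False)]
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        d = Xc[i] - Xc[j]
        diff = float(d @ beta)
        se = float(np.sqrt(max(d @ V @ d, 0.0)))
        z = diff / se if se > 0 else 0.0
        p = 1.0 if se == 0 and diff == 0 else float(2 * sps.norm.sf(abs(z)))
        rows.append({"cell_a": labels[i], "cell_b": labels[j],
                     "mean_a": float(means[i]), "mean_b": float(means[j]),
                     "diff": diff, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows)


def covariate_r2(data: pd.DataFrame, response: str, covariate: str,
                 by: str = "region", min_n: int = 3) -> dict[str, float]:
    """Squared Pearson correlation of response with a covariate, per group.

    Groups with fewer than ``min_n`` complete observations are omitted.
    Reported alongside the GEE covariate-by-region interaction test when
    asking whether running distance predicts expression region-specifically.
    """
    out: dict[str, float] = {}
    for grp_name, grp in data.groupby(by, sort=True):
        sub = grp[[response, covariate]].dropna()
        if len(sub) < min_n:
            continue
        x = sub[covariate].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[grp_name] = 0.0
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out[grp_name] = r * r
    return out
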