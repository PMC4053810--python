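"""Vectorized least-squares helpers shared across modules.

All epigenome-wide operations here fit the same design matrix to many probes
at once, so ordinary least squares is solved once via QR and broadcast across
the probe dimension instead of looping over statsmodels fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


def check_full_rank(X: np.ndarray, names: list[str], tol: float = 1e-8) -> None:
    """Raise :class:`CollinearityError` naming columns with tiny QR pivots."""
    R = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(R))
    scale = d.max() if d.max() > 0 else 1.0
    bad = [names[i] for i in range(len(d)) if d[i] < tol * scale]
    if len(d) < X.shape[1]:
        bad = names[len(d):]
    if bad:
        raise CollinearityError(
            f"collinear design columns: {bad} (rank {int((d >= tol * scale).sum())} "
            f"of {X.shape[1]})"
        )


def ols_terms(
    X: np.ndarray, Y: np.ndarray, names: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Fit Y[:, j] ~ X for every column j simultaneously.

    Returns (coef, t, p) each of shape (n_terms, n_probes), plus the residual
    degrees of freedom.  Y is observations x probes; X is observations x terms.
    """
    n, k = X.shape
    check_full_rank(X, names)
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Y)  # k x p
    resid = Y - X @ coef
    dof = n - k
    sse = np.einsum("ij,ij->j", resid, resid)
    sigma2 = sse / max(dof, 1)
    XtX_inv_diag = np.sum(np.linalg.inv(R) ** 2, axis=1)  # diag of (X'X)^-1
    se = np.sqrt(np.outer(XtX_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=max(dof, 1))
    p[se == 0] = 1.0
    return coef, t, p, dof


def r_squared(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain and adjusted R^2 of Y[:, j] ~ X (X must include an intercept)."""
    n, k = X.shape
    Q, _ = np.linalg.qr(X)
    fitted_ss = np.einsum("ij,ij->j", Q.T @ Y, Q.T @ Y)
    total_ss = np.einsum("ij,ij->j", Y, Y)
    sse = np.maximum(total_ss - fitted_ss, 0.0)
    yc = Y - Y.mean(axis=0)
    sst = np.einsum("ij,ij->j", yc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
        adj = np.where(
            (sst > 0) & (n - k > 0), 1.0 - (1.0 - r2) * (n - 1) / (n - k), np.nan
        )
    return r2, adj


def celltype_design(labels: pd.Series) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + treatment-coded cell-type dummies (first level reference)."""
    levels = list(pd.unique(labels))
    X = [np.ones(len(labels))]
    names = ["intercept"]
    for lv in levels[1:]:
        X.append((labels == lv).to_numpy(dtype=float))
        names.append(f"cell_type[{lv}]")
    return np.column_stack(X), names, levels
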