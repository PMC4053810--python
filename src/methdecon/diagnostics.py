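"""Composition-variability diagnostics.

Covers the per-probe composition ANOVA table (F statistic, p value, per-type
means and beta range across sorted samples), age/cell-type variance
partitioning in sorted data, correlation of principal components of the
methylation matrix with the principal component of estimated proportions,
per-cell-type age trends, and the conjunctive composition filter
(F-test p < 1e-4 AND beta range > 10% by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._lm import celltype_design, ols_terms, r_squared
from .deconvolution import CellProportions
from .matrix_io import BetaMatrix, ValidationError
from .reference_builder import SortedReference

logger = logging.getLogger("methdecon")

COMPOSITION_P_CUT = 1e-4
COMPOSITION_RANGE_CUT = 0.10


# ---------------------------------------------------------------------------
# per-probe composition ANOVA
# ---------------------------------------------------------------------------

def composition_anova(ref: SortedReference) -> pd.DataFrame:
    """One-way ANOVA per probe across cell-type groups.

    Returns one row per probe with Fstat, p.value, per-cell-type mean beta
    (``<type>_mean``), and the min/max/range of beta across all samples.
    Probes with zero within- and between-group variance get F = 0, p = 1.
    """
    Y = ref.beta.values.to_numpy(dtype=float)  # probes x samples
    labels = ref.labels
    groups = ref.cell_types
    n_total = Y.shape[1]
    grand = Y.mean(axis=1)

    ssb = np.zeros(Y.shape[0])
    ssw = np.zeros(Y.shape[0])
    means = {}
    for ct in groups:
        mask = (labels == ct).to_numpy()
        g = Y[:, mask]
        m = g.mean(axis=1)
        means[f"{ct}_mean"] = m
        ssb += mask.sum() * (m - grand) ** 2
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)

    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    zero_total = (ssb + ssw) <= 1e-24  # constant probe up to float noise
    F = np.where(zero_total, 0.0, F)
    p = stats.f.sf(F, df_b, df_w)
    p = np.where(zero_total, 1.0, p)
    p = np.where(np.isinf(F), 0.0, p)

    out = pd.DataFrame({"Fstat": F, "p.value": p}, index=ref.beta.probe_ids)
    for col, m in means.items():
        out[col] = m
    out["DNAm_min"] = Y.min(axis=1)
    out["DNAm_max"] = Y.max(axis=1)
    out["DNAm_range"] = out["DNAm_max"] - out["DNAm_min"]
    out.index.name = "Name"
    return out


# ---------------------------------------------------------------------------
# variance partition: age vs cell type
# ---------------------------------------------------------------------------

def variance_partition(ref: SortedReference) -> pd.DataFrame:
    """Adjusted R^2 of per-probe models (age), (cell type), (age + cell type +
    interaction), plus per-cell-type age p values.

    The interaction model fits a separate age slope and intercept per cell
    type; it is skipped with a warning when residual degrees of freedom run
    out.
    """
    if ref.ages is None or ref.ages.isna().any():
        raise ValidationError("ages are required for variance partitioning")
    Y = ref.beta.values.to_numpy(dtype=float).T  # samples x probes
    age = ref.ages.to_numpy(dtype=float)
    n = len(age)

    X_age = np.column_stack([np.ones(n), age])
    X_cell, _, levels = celltype_design(ref.labels)
    inter_cols = [
        age * (ref.labels == lv).to_numpy(dtype=float) for lv in levels[1:]
    ]
    X_full = np.column_stack([X_cell, age] + inter_cols)

    out = pd.DataFrame(index=ref.beta.probe_ids)
    _, out["adj_r2_age"] = r_squared(X_age, Y)
    _, out["adj_r2_celltype"] = r_squared(X_cell, Y)
    out["r2_age"], _ = r_squared(X_age, Y)
    out["r2_celltype"], _ = r_squared(X_cell, Y)
    if n - X_full.shape[1] >= 1:
        _, out["adj_r2_full"] = r_squared(X_full, Y)
        out["r2_full"], _ = r_squared(X_full, Y)
    else:
        warnings.warn(
            "insufficient degrees of freedom for the interaction model; skipped"
        )
        out["adj_r2_full"] = np.nan
        out["r2_full"] = np.nan

    for ct in levels:
        mask = (ref.labels == ct).to_numpy()
        if mask.sum() >= 3:
            Xc = np.column_stack([np.ones(mask.sum()), age[mask]])
            _, _, p, _ = ols_terms(Xc, Y[mask], ["intercept", "age"])
            out[f"age_p_{ct}"] = p[1]
        else:
            out[f"age_p_{ct}"] = np.nan
    out.index.name = "probe_id"
    return out


# ---------------------------------------------------------------------------
# PCA vs composition
# ---------------------------------------------------------------------------

def pc_composition_correlation(
    beta: BetaMatrix, props: CellProportions, n_pcs: int = 2
) -> pd.DataFrame:
    """Correlate methylation principal components with the composition PC1.

    Samples are the observations; probes are centered but not scaled (beta
    values already share a scale).  Returns, per methylation PC, the signed
    and absolute Pearson correlation with the first PC of the proportions
    matrix and the fraction of methylation variance the PC explains.  If the
    proportions are constant across samples the correlation is undefined and
    reported as 0 with ``degenerate=True``.
    """
    shared = beta.sample_ids[beta.sample_ids.isin(props.sample_ids)]
    if len(shared) != len(beta.sample_ids) or len(shared) != len(props.sample_ids):
        raise ValidationError("beta matrix and proportions cover different samples")
    X = beta.values[shared].to_numpy(dtype=float).T  # samples x probes
    P = props.proportions.loc[shared].to_numpy(dtype=float)

    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank; truncated to {max_rank}")
        n_pcs = max_rank
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(X)  # samples x n_pcs

    Pc = P - P.mean(axis=0)
    degenerate = not np.any(Pc.std(axis=0) > 0)
    if degenerate:
        prop_pc1 = np.zeros(X.shape[0])
    else:
        prop_pc1 = PCA(n_components=1).fit_transform(P)[:, 0]

    rows = []
    for i in range(n_pcs):
        if degenerate or scores[:, i].std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(scores[:, i], prop_pc1)[0, 1])
        rows.append(
            {
                "pc": i + 1,
                "correlation": r,
                "abs_correlation": abs(r),
                "variance_explained": float(pca.explained_variance_ratio_[i]),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("pc")


# ---------------------------------------------------------------------------
# age trends in estimated proportions
# ---------------------------------------------------------------------------

def _loess(
    x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Tricube-weighted local polynomial smoother evaluated at the data points."""
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(xs - xs[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(len(idx))
        V = np.vander(xs[idx] - xs[i], degree + 1, increasing=True)
        sw = np.sqrt(np.maximum(w, 0))
        coef = np.linalg.lstsq(V * sw[:, None], ys[idx] * sw, rcond=None)[0]
        fitted[i] = coef[0]
    out = np.empty(n)
    out[order] = fitted
    return out


def age_trend(
    props: CellProportions,
    ages: pd.Series,
    span: float = 0.75,
    degree: int = 2,
    exact_threshold: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of each cell-type proportion with age, plus a
    loess-smoothed trend curve.

    P values use the asymptotic approximation by default; for small cohorts
    set ``exact_threshold`` (e.g. 30) to switch to a permutation p value when
    n is below it.  Returns (per-cell-type stats, smoothed curves indexed by
    sample in age order).
    """
    ages = ages.reindex(props.sample_ids)
    if ages.isna().any():
        raise ValidationError("ages missing for some samples")
    if len(ages) < 3:
        raise ValidationError("need at least 3 samples for an age trend")
    P = props.normalized if props.normalized is not None else props.proportions
    a = ages.to_numpy(dtype=float)

    stats_rows = []
    curves = {}
    rng = np.random.default_rng(seed)
    for ct in props.cell_types:
        y = P[ct].to_numpy(dtype=float)
        if len(a) < exact_threshold:
            res = stats.permutation_test(
                (a, y),
                lambda x, yy: stats.spearmanr(x, yy).statistic,
                permutation_type="pairings",
                n_resamples=9999,
                rng=rng,
            )
            rho, p = float(res.statistic), float(res.pvalue)
        else:
            sp = stats.spearmanr(a, y)
            rho, p = float(sp.statistic), float(sp.pvalue)
        stats_rows.append({"cell_type": ct, "spearman_rho": rho, "p": p})
        curves[ct] = _loess(a, y, span=span, degree=degree)
    order = np.argsort(a)
    curve_df = pd.DataFrame(curves, index=props.sample_ids).iloc[order]
    curve_df.insert(0, "age", a[order])
    return pd.DataFrame(stats_rows).set_index("cell_type"), curve_df


# ---------------------------------------------------------------------------
# composition filter
# ---------------------------------------------------------------------------

def composition_filter(
    candidates: Sequence[str] | pd.Index,
    comp_stats: pd.DataFrame,
    p_cut: float = COMPOSITION_P_CUT,
    range_cut: float = COMPOSITION_RANGE_CUT,
    strict: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Drop candidate probes strongly associated with cell composition.

    A probe is removed only when BOTH its composition-ANOVA p value is below
    ``p_cut`` AND its beta range across sorted samples exceeds ``range_cut``.
    Probes absent from the stats table raise in strict mode and pass through
    with a warning otherwise.  Returns (retained probes, removal report).
    """
    candidates = pd.Index(candidates)
    missing = candidates[~candidates.isin(comp_stats.index)]
    if len(missing) and strict:
        raise ValidationError(
            f"{len(missing)} candidate probes absent from composition stats, "
            f"e.g. {list(missing[:5])}"
        )
    if len(missing):
        warnings.warn(f"{len(missing)} probes absent from stats; passed through")
    present = candidates[candidates.isin(comp_stats.index)]
    sub = comp_stats.loc[present]
    removed_mask = (sub["p.value"] < p_cut) & (sub["DNAm_range"] > range_cut)
    retained = list(present[~removed_mask]) + list(missing)
    report = pd.DataFrame(
        {
            "probe_id": present[removed_mask],
            "p.value": sub.loc[removed_mask, "p.value"].to_numpy(),
            "DNAm_range": sub.loc[removed_mask, "DNAm_range"].to_numpy(),
        }
    ).set_index("probe_id")
    logger.info(
        "composition filter removed %d of %d candidates (p<%g & range>%g)",
        int(removed_mask.sum()),
        len(candidates),
        p_cut,
        range_cut,
    )
    return retained, report
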