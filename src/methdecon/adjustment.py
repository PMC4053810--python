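"""Confounding-handling strategies for epigenome-wide association with age.

Three routes are compared: a univariate per-probe regression of beta on age
(optionally with known covariates such as processing plate); a "naive"
adjustment that additionally includes estimated cell proportions as
covariates; and a two-step remove-unwanted-variation (RUV) adjustment that
derives k surrogate covariates from the singular vectors of a negative-control
probe submatrix — the signature probes, which discriminate cell types but are
unassociated with age — and includes them in the second-stage regressions.

The module also implements the two-cell-type CETS transform
T(Y) = Y + (1 - pi) (mubar_N - mubar_G) and its closed-form bias
decomposition T(Y) = mu_N + (1 - pi)[(mubar_N - mu_N) - (mubar_G - mu_G)] + eps,
which shows the transform recovers the pure neuronal profile only when the
individual deviations from the average profiles agree across cell types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._lm import CollinearityError, ols_terms
from .deconvolution import CellProportions
from .matrix_io import BetaMatrix, ValidationError

logger = logging.getLogger("methdecon")

FDR_LEVEL = 0.05


@dataclass
class AssociationResult:
    """Per-probe age-association statistics for one method.

    ``table`` has columns estimate (beta units per year), t, p, q (BH-adjusted
    p), significant (q < fdr_level).  ``fdr_threshold_t`` is the |t| cutoff
    attaining FDR < ``fdr_level`` (NaN when nothing is significant).
    """

    table: pd.DataFrame
    method: str
    fdr_level: float
    fdr_threshold_t: float
    meta: dict

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_tsv(self, path, header_lines=()) -> None:
        out = self.table.copy()
        out["method"] = self.method
        out.index.name = "probe_id"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t")


def _covariate_design(
    n: int, age: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + age + expanded covariates; age is always column 1."""
    cols = [np.ones(n), age]
    names = ["intercept", "age"]
    if covariates is not None:
        for col in covariates.columns:
            s = covariates[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                levels = list(pd.unique(s))
                for lv in levels[1:]:
                    cols.append((s == lv).to_numpy(dtype=float))
                    names.append(f"{col}[{lv}]")
            else:
                cols.append(s.to_numpy(dtype=float))
                names.append(col)
    return np.column_stack(cols), names


def _ewas(
    beta: BetaMatrix,
    age: pd.Series,
    covariates: pd.DataFrame | None,
    method: str,
    fdr_level: float,
    extra_meta: dict | None = None,
) -> AssociationResult:
    age = age.reindex(beta.sample_ids)
    if age.isna().any():
        raise ValidationError("age missing for some samples")
    if covariates is not None:
        covariates = covariates.reindex(beta.sample_ids)
        if covariates.isna().any().any():
            raise ValidationError("covariate values missing for some samples")
    Y = beta.values.to_numpy(dtype=float).T  # samples x probes
    X, names = _covariate_design(len(age), age.to_numpy(dtype=float), covariates)
    coef, t, p, dof = ols_terms(X, Y, names)

    est, tt, pp = coef[1], t[1], p[1]
    reject, q, _, _ = multipletests(pp, alpha=fdr_level, method="fdr_bh")
    thr = float(np.abs(tt[reject]).min()) if reject.any() else float("nan")
    table = pd.DataFrame(
        {"estimate": est, "t": tt, "p": pp, "q": q, "significant": reject},
        index=beta.probe_ids,
    )
    meta = {"design_columns": names, "residual_dof": dof}
    meta.update(extra_meta or {})
    logger.info(
        "%s EWAS: %d/%d probes significant at FDR<%g (|t| cutoff %.3g)",
        method,
        int(reject.sum()),
        len(pp),
        fdr_level,
        thr,
    )
    return AssociationResult(
        table=table,
        method=method,
        fdr_level=fdr_level,
        fdr_threshold_t=thr,
        meta=meta,
    )


def univariate_ewas(
    beta: BetaMatrix,
    age: pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr_level: float = FDR_LEVEL,
) -> AssociationResult:
    """Per-probe regression of beta on age (plus optional known covariates)."""
    return _ewas(beta, age, covariates, "univariate", fdr_level)


def naive_adjust(
    beta: BetaMatrix,
    age: pd.Series,
    props: CellProportions,
    covariates: pd.DataFrame | None = None,
    fdr_level: float = FDR_LEVEL,
) -> AssociationResult:
    """Univariate EWAS with estimated cell proportions as extra covariates.

    The last declared cell-type column is dropped to avoid the simplex
    collinearity (proportions summing to one against the intercept); the
    dropped column is recorded in the result metadata.
    """
    P = props.proportions.reindex(beta.sample_ids)
    if P.isna().any().any():
        raise ValidationError("proportions missing for some samples")
    dropped = props.cell_types[-1]
    P = P.drop(columns=dropped)
    # constant proportion columns carry no adjustment information and would
    # be collinear with the intercept; with fully constant composition the
    # model reduces to the univariate one
    constant = [c for c in P.columns if P[c].nunique() == 1]
    P = P.drop(columns=constant)
    cov_parts = [df for df in (covariates, P if P.shape[1] else None) if df is not None]
    cov = pd.concat(cov_parts, axis=1) if cov_parts else None
    res = _ewas(
        beta,
        age,
        cov,
        "naive",
        fdr_level,
        {"dropped_cell_type": dropped, "dropped_constant_columns": constant},
    )
    return res


def ruv2_adjust(
    beta: BetaMatrix,
    age: pd.Series,
    control_probes,
    k: int,
    covariates: pd.DataFrame | None = None,
    fdr_level: float = FDR_LEVEL,
) -> AssociationResult:
    """Two-step RUV: surrogate covariates from control probes, then EWAS.

    Step 1 takes the top ``k`` right-singular vectors of the per-probe
    centered control-probe submatrix as sample-level surrogate covariates;
    step 2 regresses every probe on age + covariates + surrogates.  Control
    probes must be a subset of the beta probes and assumed unassociated with
    the outcome; ``k = 0`` reproduces the univariate analysis.
    """
    control_probes = pd.Index(control_probes)
    missing = control_probes[~control_probes.isin(beta.probe_ids)]
    if len(missing):
        raise ValidationError(
            f"{len(missing)} control probes absent from beta matrix, "
            f"e.g. {list(missing[:5])}"
        )
    n = len(beta.sample_ids)
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the sample count {n}")
    if k > len(control_probes):
        raise ValidationError(
            f"k={k} exceeds the number of control probes {len(control_probes)}"
        )
    if k == 0:
        surrogates = None
    else:
        C = beta.values.loc[control_probes].to_numpy(dtype=float)
        C = C - C.mean(axis=1, keepdims=True)  # center each control probe
        _, _, vt = np.linalg.svd(C, full_matrices=False)
        surrogates = pd.DataFrame(
            vt[:k].T,
            index=beta.sample_ids,
            columns=[f"ruv_{i + 1}" for i in range(k)],
        )
    cov = (
        surrogates
        if covariates is None
        else (covariates if surrogates is None else pd.concat([covariates, surrogates], axis=1))
    )
    return _ewas(
        beta,
        age,
        cov,
        "ruv2",
        fdr_level,
        {"k": k, "n_control_probes": len(control_probes)},
    )


def scree_singular_values(beta: BetaMatrix, control_probes) -> np.ndarray:
    """Singular values of the centered control submatrix (a scree-plot aid
    for choosing k)."""
    C = beta.values.loc[pd.Index(control_probes)].to_numpy(dtype=float)
    C = C - C.mean(axis=1, keepdims=True)
    return np.linalg.svd(C, compute_uv=False)


# ---------------------------------------------------------------------------
# CETS transform and its bias
# ---------------------------------------------------------------------------

@dataclass
class CetsProfiles:
    """Two-cell-type mixture profiles in the observed-signal decomposition
    Y_i = pi_i mu_iN + (1 - pi_i) mu_iG + eps_i.

    Arrays are samples x probes except the average profiles (length probes)
    and ``pi`` (length samples).  ``mu_bar_N`` / ``mu_bar_G`` are the
    population-average neuron/glia profiles the transform uses; ``mu_N`` /
    ``mu_G`` are the individual profiles.  The measurement error ``eps`` may
    push transformed values outside [0, 1]; such values are flagged, never
    clamped.
    """

    Y: np.ndarray
    pi: np.ndarray
    mu_N: np.ndarray
    mu_G: np.ndarray
    mu_bar_N: np.ndarray
    mu_bar_G: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValidationError("pi must lie in [0, 1]")
        for name in ("mu_N", "mu_G", "mu_bar_N", "mu_bar_G"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValidationError(f"{name} values outside [0, 1]")

    @classmethod
    def assemble(cls, pi, mu_N, mu_G, mu_bar_N, mu_bar_G, eps) -> "CetsProfiles":
        """Build Y from the mixture decomposition (synthetic setting)."""
        pi = np.asarray(pi, dtype=float)
        Y = pi[:, None] * mu_N + (1.0 - pi)[:, None] * mu_G + eps
        return cls(
            Y=Y,
            pi=pi,
            mu_N=np.asarray(mu_N, dtype=float),
            mu_G=np.asarray(mu_G, dtype=float),
            mu_bar_N=np.asarray(mu_bar_N, dtype=float),
            mu_bar_G=np.asarray(mu_bar_G, dtype=float),
            eps=np.asarray(eps, dtype=float),
        )


def cets_transform(profiles: CetsProfiles) -> np.ndarray:
    """T(Y_i) = Y_i + (1 - pi_i) (mu_bar_N - mu_bar_G), elementwise."""
    shift = (1.0 - profiles.pi)[:, None] * (
        profiles.mu_bar_N - profiles.mu_bar_G
    )[None, :]
    out = profiles.Y + shift
    n_outside = int(np.sum((out < 0) | (out > 1)))
    if n_outside:
        logger.info(
            "cets_transform: %d transformed values fall outside [0, 1]", n_outside
        )
    return out


def cets_bias(profiles: CetsProfiles) -> np.ndarray:
    """Closed-form departure of the transform from the pure neuronal profile:

    T(Y_i) - mu_iN = (1 - pi_i)[(mu_bar_N - mu_iN) - (mu_bar_G - mu_iG)] + eps_i.

    The bias reduces to the measurement error alone exactly when the
    individual deviations from the average profiles are equal across the two
    cell types.
    """
    w = (1.0 - profiles.pi)[:, None]
    dev_N = profiles.mu_bar_N[None, :] - profiles.mu_N
    dev_G = profiles.mu_bar_G[None, :] - profiles.mu_G
    return w * (dev_N - dev_G) + profiles.eps
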