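"""Constrained projection of mixed-tissue profiles onto a cell-type signature.

Each whole-tissue sample's beta profile y over the signature probes is modeled
as y = X w + e, where X holds the per-cell-type mean profiles and w the cell
proportions.  w is found by least squares under nonnegativity (default), or
additionally the sum-to-one constraint ("simplex" mode).  In nonnegative mode
a post-hoc normalized copy w / sum(w) is reported alongside the raw weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .matrix_io import BetaMatrix, ValidationError
from .reference_builder import (
    ReferenceSignature,
    SortedReference,
    age_prefilter,
    one_vs_rest_tstats,
    select_signature,
)

logger = logging.getLogger("methdecon")

#: minimum fraction of signature probes that must be present in the target
MIN_SIGNATURE_OVERLAP = 0.80


@dataclass
class CellProportions:
    """Estimated per-sample cell-type fractions.

    ``proportions`` is samples x cell types.  In "nonneg" mode the raw
    nonnegative weights are stored and ``normalized`` carries the row-sum-1
    copy; in "simplex" mode both coincide.  ``residual_norm`` holds per-sample
    ||y - Xw||.
    """

    proportions: pd.DataFrame
    constraint_mode: str
    residual_norm: pd.Series
    normalized: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.proportions.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)

    def to_tsv(self, path, header_lines=()) -> None:
        out = self.proportions.copy()
        out["residual_norm"] = self.residual_norm
        out.index.name = "sample_id"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _simplex_lsq(A: np.ndarray, y: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """min ||Aw - y||^2  s.t.  w >= 0, sum(w) = 1, by an active-set method.

    Solves the equality-constrained KKT system on the passive set; variables
    driven negative are clamped to the active set, and active variables with
    negative multipliers are released, until the KKT conditions hold.
    """
    k = A.shape[1]
    AtA = A.T @ A
    Aty = A.T @ y
    passive = np.ones(k, dtype=bool)
    ones = np.ones(k)
    for _ in range(4 * k + 10):
        idx = np.flatnonzero(passive)
        m = len(idx)
        # KKT: [2 AtA_PP, 1; 1', 0] [w_P; lam] = [2 Aty_P; 1]
        kkt = np.zeros((m + 1, m + 1))
        kkt[:m, :m] = 2.0 * AtA[np.ix_(idx, idx)]
        kkt[:m, m] = 1.0
        kkt[m, :m] = 1.0
        rhs = np.concatenate([2.0 * Aty[idx], [1.0]])
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        w_p, lam = sol[:m], sol[m]
        if m > 1 and w_p.min() < -tol:
            passive[idx[np.argmin(w_p)]] = False
            continue
        w = np.zeros(k)
        w[idx] = np.maximum(w_p, 0.0)
        # stationarity: 2 A'(Aw - y) + lam*1 - mu = 0, mu >= 0 on active set
        grad = 2.0 * (AtA @ w - Aty)
        mu = grad + lam * ones
        active = ~passive
        if active.any() and mu[active].min() < -tol * max(1.0, np.abs(mu).max()):
            j = np.flatnonzero(active)[np.argmin(mu[active])]
            passive[j] = True
            continue
        return w
    warnings.warn("simplex solver hit iteration cap; returning last iterate")
    return w


def _solve_proportions(X: np.ndarray, y: np.ndarray, mode: str) -> np.ndarray:
    if mode == "nonneg":
        w, _ = nnls(X, y)
        return w
    if mode == "simplex":
        return _simplex_lsq(X, y)
    raise ValueError(f"unknown constraint mode: {mode!r}")


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_proportions(
    target: BetaMatrix, signature: ReferenceSignature, mode: str = "nonneg"
) -> CellProportions:
    """Estimate cell-type proportions for every sample in ``target``.

    The target is restricted internally to signature probes; at least 80% of
    them must be present, else an error lists the missing probes.  Signature
    rows absent below that threshold are dropped with a warning.
    """
    sig_probes = signature.probe_ids
    present = sig_probes[sig_probes.isin(target.probe_ids)]
    missing = sig_probes[~sig_probes.isin(target.probe_ids)]
    if len(present) < MIN_SIGNATURE_OVERLAP * len(sig_probes):
        raise ValidationError(
            f"only {len(present)}/{len(sig_probes)} signature probes present in "
            f"target (need >={MIN_SIGNATURE_OVERLAP:.0%}); missing e.g. "
            f"{list(missing[:10])}"
        )
    if len(missing):
        warnings.warn(
            f"{len(missing)} signature probes missing from target; dropped"
        )
    X = signature.means.loc[present].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "signature design is rank deficient: cell-type profiles are not "
            "linearly independent over the available probes"
        )
    Y = target.values.loc[present].to_numpy(dtype=float)

    k = X.shape[1]
    W = np.empty((Y.shape[1], k))
    resid = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        w = _solve_proportions(X, Y[:, j], mode)
        W[j] = np.maximum(w, 0.0)  # clamp solver noise at -1e-12 scale
        resid[j] = np.linalg.norm(Y[:, j] - X @ w)

    props = pd.DataFrame(W, index=target.sample_ids, columns=signature.cell_types)
    resid_s = pd.Series(resid, index=target.sample_ids, name="residual_norm")
    if mode == "simplex":
        return CellProportions(
            proportions=props,
            constraint_mode="simplex",
            residual_norm=resid_s,
            normalized=props,
        )
    sums = props.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = props.div(sums.where(sums > 0), axis=0).fillna(0.0)
    return CellProportions(
        proportions=props,
        constraint_mode="nonneg (normalized copy reported)",
        residual_norm=resid_s,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation of the reference
# ---------------------------------------------------------------------------

def crossvalidate_reference(
    ref: SortedReference,
    p_threshold: float = 1e-8,
    n_hyper: int = 50,
    n_hypo: int = 50,
    use_age_prefilter: bool = False,
    alpha: float = 0.05,
    mode: str = "nonneg",
) -> pd.DataFrame:
    """Leave one sample per cell type out, retrain, and predict the held-out.

    Fold f holds out the f-th replicate of every cell type; the signature is
    rebuilt on the remaining samples only and the held-out samples are
    projected.  For sorted samples the true composition is the unit vector on
    their own type, so the returned frame carries the estimated proportions
    (normalized), the sample's true type, and ``own_type_proportion`` as the
    concordance measure.  Requires >=3 samples per cell type.
    """
    counts = ref.labels.value_counts()
    if (counts < 3).any():
        raise ValidationError(
            "leave-one-out cross-validation needs >=3 samples per cell type "
            "(2 must remain for training)"
        )
    n_folds = int(counts.min())
    rows = []
    for f in range(n_folds):
        held = [
            ref.labels.index[(ref.labels == ct).to_numpy()][f]
            for ct in ref.cell_types
        ]
        train = ref.drop_samples(held)
        excluded = (
            age_prefilter(train, alpha=alpha) if use_age_prefilter else ()
        )
        sig = select_signature(
            one_vs_rest_tstats(train),
            train,
            p_threshold=p_threshold,
            n_hyper=n_hyper,
            n_hypo=n_hypo,
            excluded=excluded,
        )
        test = BetaMatrix(values=ref.beta.values[held])
        est = project_proportions(test, sig, mode=mode)
        props = est.normalized if est.normalized is not None else est.proportions
        for s in held:
            true_ct = ref.labels.loc[s]
            row = props.loc[s].to_dict()
            row.update(
                sample_id=s,
                fold=f,
                true_cell_type=true_ct,
                own_type_proportion=props.loc[s, true_ct],
            )
            rows.append(row)
    out = pd.DataFrame(rows).set_index("sample_id")
    logger.info(
        "cross-validation: mean own-type proportion %.4f over %d held-out samples",
        out["own_type_proportion"].mean(),
        len(out),
    )
    return out
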