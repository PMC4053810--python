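"""Signature-probe selection from flow-sorted reference methylation data.

The reference-building procedure mirrors the regression-calibration approach
for whole-blood deconvolution: probes associated with age are removed first,
one-vs-rest t statistics are computed per cell type, and per cell type the
most differentially methylated probes passing a stringent p-value threshold
are kept — by default 50 hypermethylated and 50 hypomethylated per type, so a
clean six-cell-type reference yields a 600-probe signature.  Per-cell-type
mean beta profiles over the selected probes form the design matrix of the
downstream constrained projection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import celltype_design, ols_terms
from .matrix_io import BetaMatrix, ValidationError

logger = logging.getLogger("methdecon")


@dataclass
class SortedReference:
    """Flow-sorted reference samples: beta matrix + per-sample labels/ages.

    At least two samples per cell type are required so within-type variance
    is estimable.
    """

    beta: BetaMatrix
    labels: pd.Series  # cell type per sample, indexed by sample id
    ages: pd.Series | None = None  # years, indexed by sample id

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.beta.sample_ids)
        if self.labels.isna().any():
            raise ValidationError("cell-type label missing for some samples")
        counts = self.labels.value_counts()
        if (counts < 2).any():
            few = counts[counts < 2].index.tolist()
            raise ValidationError(
                f"need >=2 samples per cell type for variance estimation; "
                f"too few in {few}"
            )
        if self.ages is not None:
            self.ages = self.ages.reindex(self.beta.sample_ids)

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.labels))

    def drop_samples(self, sample_ids: Iterable[str]) -> "SortedReference":
        keep = self.beta.sample_ids[~self.beta.sample_ids.isin(list(sample_ids))]
        return SortedReference(
            beta=BetaMatrix(values=self.beta.values[keep]),
            labels=self.labels.loc[keep],
            ages=None if self.ages is None else self.ages.loc[keep],
        )


@dataclass
class ReferenceSignature:
    """Selected discriminating probes with per-cell-type mean beta profiles.

    ``means`` (signature probes x cell types) is the design matrix X of the
    proportion projection; ``selection_meta`` records per probe the target
    cell type, direction (hyper/hypo in that type), t statistic and p value.
    """

    means: pd.DataFrame
    selection_meta: pd.DataFrame

    @property
    def probe_ids(self) -> pd.Index:
        return self.means.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.means.columns)

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        out = self.selection_meta.join(
            self.means.rename(columns=lambda c: f"{c}_mean")
        )
        out.index.name = "probe_id"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceSignature":
        table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        mean_cols = [c for c in table.columns if c.endswith("_mean")]
        means = table[mean_cols].rename(columns=lambda c: c[: -len("_mean")])
        meta = table[[c for c in table.columns if c not in mean_cols]]
        return cls(means=means, selection_meta=meta)


# ---------------------------------------------------------------------------
# age pre-filter
# ---------------------------------------------------------------------------

def age_prefilter(
    ref: SortedReference, alpha: float = 0.05, per_cell_type: bool = False
) -> pd.Index:
    """Probes whose methylation associates with age at p <= alpha.

    Pooled mode (default) regresses each probe's beta on age with cell type
    as an additive covariate.  ``per_cell_type`` instead fits a separate
    age regression within each cell type and flags a probe if any within-type
    age term reaches alpha.  Probes with zero variance get p = 1 and are never
    excluded.  Returns the probe ids to exclude from signature selection.
    """
    if ref.ages is None or ref.ages.isna().any():
        raise ValidationError(
            "ages are required for the age pre-filter; skip the filter if absent"
        )
    Y = ref.beta.values.to_numpy(dtype=float).T  # samples x probes
    age = ref.ages.to_numpy(dtype=float)

    if per_cell_type:
        flagged = np.zeros(Y.shape[1], dtype=bool)
        for ct in ref.cell_types:
            mask = (ref.labels == ct).to_numpy()
            X = np.column_stack([np.ones(mask.sum()), age[mask]])
            _, _, p, _ = ols_terms(X, Y[mask], ["intercept", "age"])
            flagged |= p[1] <= alpha
        return ref.beta.probe_ids[flagged]

    Xct, names, _ = celltype_design(ref.labels)
    X = np.column_stack([Xct, age])
    _, _, p, _ = ols_terms(X, Y, names + ["age"])
    return ref.beta.probe_ids[p[-1] <= alpha]


# ---------------------------------------------------------------------------
# one-vs-rest t statistics
# ---------------------------------------------------------------------------

def one_vs_rest_tstats(
    ref: SortedReference, equal_var: bool = False
) -> dict[str, pd.DataFrame]:
    """Per-probe t statistics comparing each cell type with all others pooled.

    Welch's unequal-variance test by default (``equal_var=True`` pools).
    Probes with zero variance in both groups get t = 0, p = 1.  Returns, per
    cell type, a frame with columns t, p, mean_target, mean_rest, effect
    (= mean_target - mean_rest on the beta scale).
    """
    Y = ref.beta.values.to_numpy(dtype=float)  # probes x samples
    out: dict[str, pd.DataFrame] = {}
    for ct in ref.cell_types:
        mask = (ref.labels == ct).to_numpy()
        a, b = Y[:, mask], Y[:, ~mask]
        n1, n2 = a.shape[1], b.shape[1]
        m1, m2 = a.mean(axis=1), b.mean(axis=1)
        v1 = a.var(axis=1, ddof=1)
        v2 = b.var(axis=1, ddof=1)
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            denom2 = sp2 * (1 / n1 + 1 / n2)
            df = np.full(Y.shape[0], n1 + n2 - 2, dtype=float)
        else:
            se1, se2 = v1 / n1, v2 / n2
            denom2 = se1 + se2
            with np.errstate(divide="ignore", invalid="ignore"):
                df = denom2**2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom2 > 0, (m1 - m2) / np.sqrt(denom2), 0.0)
            p = 2.0 * stats.t.sf(np.abs(t), df=np.where(df > 0, df, 1.0))
        # degenerate probes: no variance anywhere -> t undefined, reported
        # null; unless the means still differ (noiseless data), where the
        # separation is perfect.  Thresholds absorb float accumulation noise
        # on the [0,1] beta scale.
        zero_var = denom2 <= 1e-24
        perfect = zero_var & (np.abs(m1 - m2) > 1e-12)
        t[perfect] = np.sign((m1 - m2)[perfect]) * np.inf
        p[perfect] = 0.0
        t[zero_var & ~perfect] = 0.0
        p[zero_var & ~perfect] = 1.0
        out[ct] = pd.DataFrame(
            {
                "t": t,
                "p": p,
                "mean_target": m1,
                "mean_rest": m2,
                "effect": m1 - m2,
            },
            index=ref.beta.probe_ids,
        )
    return out


# ---------------------------------------------------------------------------
# signature selection
# ---------------------------------------------------------------------------

def select_signature(
    tstats: dict[str, pd.DataFrame],
    ref: SortedReference,
    p_threshold: float = 1e-8,
    n_hyper: int = 50,
    n_hypo: int = 50,
    excluded: Iterable[str] = (),
    rank_by: str = "effect",
) -> ReferenceSignature:
    """Pick the most discriminating probes per cell type and build the design.

    Among probes with p < ``p_threshold`` (and not in ``excluded``), each cell
    type contributes its top ``n_hyper`` hypermethylated (positive effect) and
    ``n_hypo`` hypomethylated probes ranked by absolute effect size — the
    beta-scale difference in group means by default (``rank_by='t'`` ranks by
    the t statistic instead).  Ties break by larger |t| then probe id.  If a
    probe is picked for two cell types it is kept once, credited to the first
    cell type in declared order, with a warning.  Cell types with fewer
    passing probes than requested contribute all that pass, with a warning.
    Mean profiles are recomputed on the final probe set.
    """
    if rank_by not in ("effect", "t"):
        raise ValueError("rank_by must be 'effect' or 't'")
    excluded = set(excluded)
    chosen: dict[str, dict] = {}
    for ct in ref.cell_types:
        tab = tstats[ct]
        ok = tab[(tab["p"] < p_threshold) & ~tab.index.isin(excluded)]
        key = ok[rank_by].abs() if rank_by == "t" else ok["effect"].abs()
        # deterministic ordering: primary key desc, |t| desc, probe id asc
        order = ok.assign(_key=key, _abst=ok["t"].abs())
        order = order.iloc[
            np.lexsort(
                (order.index.to_numpy(), -order["_abst"].to_numpy(), -order["_key"].to_numpy())
            )
        ]
        for direction, want in (("hyper", n_hyper), ("hypo", n_hypo)):
            sub = order[order["effect"] > 0] if direction == "hyper" else order[
                order["effect"] < 0
            ]
            got = sub.head(want)
            if len(got) < want:
                warnings.warn(
                    f"{ct}: only {len(got)} {direction}methylated probes pass "
                    f"p < {p_threshold} (requested {want})",
                    stacklevel=2,
                )
            for probe, row in got.iterrows():
                if probe in chosen:
                    warnings.warn(
                        f"probe {probe} selected for both "
                        f"{chosen[probe]['target_cell_type']} and {ct}; kept once",
                        stacklevel=2,
                    )
                    continue
                chosen[probe] = {
                    "target_cell_type": ct,
                    "direction": direction,
                    "t": row["t"],
                    "p": row["p"],
                }
    if not chosen:
        raise ValidationError("no probes passed the selection threshold")
    meta = pd.DataFrame.from_dict(chosen, orient="index")
    meta.index.name = "probe_id"
    means = estimate_reference_means(ref, meta.index)
    logger.info(
        "selected %d signature probes across %d cell types",
        len(meta),
        len(ref.cell_types),
    )
    return ReferenceSignature(means=means, selection_meta=meta)


def estimate_reference_means(
    ref: SortedReference, probes: Sequence[str] | pd.Index
) -> pd.DataFrame:
    """Per-probe, per-cell-type mean beta across that type's samples.

    Equivalent to the cell-type coefficients of a per-probe no-intercept
    linear model on cell-type indicator columns.
    """
    probes = pd.Index(probes)
    missing = probes[~probes.isin(ref.beta.probe_ids)]
    if len(missing):
        raise ValidationError(f"probes absent from reference: {list(missing[:5])}")
    sub = ref.beta.values.loc[probes]
    means = {
        ct: sub.loc[:, (ref.labels == ct).to_numpy()].mean(axis=1)
        for ct in ref.cell_types
    }
    return pd.DataFrame(means, index=probes)


def detect_outlier_samples(ref: SortedReference, n_mad: float = 3.0) -> list[str]:
    """Optional automated outlier rule (off by default in the pipeline).

    Flags samples whose Pearson correlation to their own cell-type centroid
    falls more than ``n_mad`` MADs below the median within-type correlation.
    Intended as an aid for choosing an explicit leave-out list; never removes
    anything by itself.
    """
    vals = ref.beta.values
    flagged: list[str] = []
    for ct in ref.cell_types:
        cols = vals.columns[(ref.labels == ct).to_numpy()]
        centroid = vals[cols].mean(axis=1)
        cors = np.array([np.corrcoef(vals[c], centroid)[0, 1] for c in cols])
        med = np.median(cors)
        mad = np.median(np.abs(cors - med))
        if mad == 0:
            continue
        flagged.extend(cols[cors < med - n_mad * mad])
    return flagged
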