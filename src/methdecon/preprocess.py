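"""Across-array normalization, beta computation, and annotation-based filtering.

Intensities are quantile-normalized across arrays within the methylated and
unmethylated channels separately.  Methylation is then expressed on the logit
scale as log2(M/U) and mapped to the beta scale 2^x / (1 + 2^x), which after
flooring equals M / (M + U) exactly; no +100 offset is used anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix_io import (
    SEX_CHROMOSOMES,
    BetaMatrix,
    ChannelMatrix,
    ProbeAnnotation,
    ValidationError,
)

logger = logging.getLogger("methdecon")

#: order in which filter criteria are applied; each probe is counted once,
#: under the first criterion it matches
FILTER_CRITERIA = ("sex_chromosomes", "snp_at_cpg", "snp_at_sbe", "snp_in_probe")


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the mean-of-order-statistics distribution.

    Each column's values are replaced by the across-column mean of the sorted
    values at the same rank; within-column ranks are preserved.  Ties are
    resolved by averaging the target values across tied ranks, which makes the
    transform deterministic.
    """
    if df.isna().any().any():
        raise ValidationError("cannot quantile-normalize a matrix with missing values")
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_channels(channels: ChannelMatrix) -> ChannelMatrix:
    """Quantile-normalize M and U across arrays, each channel separately."""
    return ChannelMatrix(
        M=quantile_normalize(channels.M), U=quantile_normalize(channels.U)
    )


def compute_beta(channels: ChannelMatrix, floor: float = 1.0) -> BetaMatrix:
    """Beta values via the logit route: floor intensities, x = log2(M/U),
    beta = 2^x / (1 + 2^x) = M / (M + U).

    The floor (default 1.0 intensity unit) keeps the log defined at zero
    intensities while perturbing real signal minimally.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    m = np.maximum(channels.M.to_numpy(dtype=float), floor)
    u = np.maximum(channels.U.to_numpy(dtype=float), floor)
    x = np.log2(m / u)
    beta = np.exp2(x) / (1.0 + np.exp2(x))
    return BetaMatrix(
        values=pd.DataFrame(
            beta, index=channels.probe_ids, columns=channels.sample_ids
        )
    )


@dataclass
class FilterReport:
    """Per-criterion drop counts, in application order."""

    counts: dict[str, int] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(self.counts), "n_dropped": list(self.counts.values())}
        )


def filter_probes(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    policy: set[str] | frozenset[str] | list[str] = frozenset(),
    strict: bool = True,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove probes matching any selected annotation criterion.

    ``policy`` selects among ``sex_chromosomes``, ``snp_at_cpg``,
    ``snp_at_sbe``, ``snp_in_probe``.  Criteria are applied in that order and
    each probe is counted once, under the first criterion it matches.  Probes
    absent from the annotation raise in strict mode and are dropped with a
    warning otherwise.
    """
    policy = set(policy)
    unknown = policy - set(FILTER_CRITERIA)
    if unknown:
        raise ValueError(f"unknown filter criteria: {sorted(unknown)}")

    probes = beta.probe_ids
    missing = probes[~probes.isin(annotation.probe_ids)]
    if len(missing):
        if strict:
            raise ValidationError(
                f"{len(missing)} probes absent from annotation, e.g. {list(missing[:5])}"
            )
        logger.warning("dropping %d probes absent from annotation", len(missing))
    present = probes[probes.isin(annotation.probe_ids)]
    ann = annotation.table.loc[present]

    report = FilterReport(counts={c: 0 for c in FILTER_CRITERIA if c in policy})
    matched = pd.Series(False, index=present)
    for criterion in FILTER_CRITERIA:
        if criterion not in policy:
            continue
        if criterion == "sex_chromosomes":
            hits = ann["chromosome"].isin(SEX_CHROMOSOMES)
        else:
            hits = ann[criterion]
        new = hits & ~matched
        report.counts[criterion] = int(new.sum())
        matched |= hits

    keep = present[~matched]
    report.dropped = list(present[matched]) + list(missing)
    logger.info(
        "filter_probes: retained %d of %d probes (%s)",
        len(keep),
        len(probes),
        report.counts,
    )
    return BetaMatrix(values=beta.values.loc[keep]), report
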