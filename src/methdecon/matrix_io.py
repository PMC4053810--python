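"""Tabular I/O and index alignment for methylation matrices.

All matrices are probes x samples: the first column holds probe identifiers,
the header row holds sample identifiers.  Input delimiters are auto-detected
between tab and comma; written output is always tab-separated.  Lines starting
with ``#`` are treated as comments (the CLI writes provenance headers there).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("methdecon")

VALID_CHROMOSOMES = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)
SEX_CHROMOSOMES = frozenset(["chrX", "chrY"])


class ValidationError(ValueError):
    """Input data violates a type invariant (range, sign, missingness)."""


class AlignmentError(ValueError):
    """Probe or sample identifiers do not line up between inputs."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ChannelMatrix:
    """Paired methylated/unmethylated intensity matrices (probes x samples).

    Invariants: shared probe and sample indices, non-negative intensities,
    no missing values.
    """

    M: pd.DataFrame
    U: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.M.index.equals(self.U.index):
            raise AlignmentError(
                "M and U probe indices differ: "
                + _diff_msg(self.M.index, self.U.index)
            )
        if not self.M.columns.equals(self.U.columns):
            raise AlignmentError(
                "M and U sample indices differ: "
                + _diff_msg(self.M.columns, self.U.columns)
            )
        for name, df in (("M", self.M), ("U", self.U)):
            _check_unique(df.index, f"{name} probe ids")
            _check_unique(df.columns, f"{name} sample ids")
            if df.isna().any().any():
                raise ValidationError(f"{name} channel contains missing values")
            if (df.values < 0).any():
                raise ValidationError(f"{name} channel contains negative intensities")

    @property
    def probe_ids(self) -> pd.Index:
        return self.M.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.M.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape


@dataclass
class BetaMatrix:
    """Proportion-methylation matrix in [0, 1] (probes x samples)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        if self.values.isna().any().any():
            raise ValidationError("beta matrix contains missing values")
        v = self.values.values
        if (v < 0).any() or (v > 1).any():
            bad = self.values.index[((v < 0) | (v > 1)).any(axis=1)]
            raise ValidationError(
                f"beta values outside [0, 1] at {len(bad)} probe(s), "
                f"e.g. {list(bad[:5])}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeAnnotation:
    """Per-probe annotation: chromosome, SNP flags, optional gene id.

    ``table`` is indexed by probe_id with columns ``chromosome``,
    ``snp_at_cpg``, ``snp_at_sbe``, ``snp_in_probe`` (booleans) and optionally
    ``gene_id`` (may hold several ids separated by ``;``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "annotation probe ids")
        if "chromosome" not in self.table.columns:
            raise ValidationError("annotation lacks a 'chromosome' column")
        bad = set(self.table["chromosome"].dropna()) - VALID_CHROMOSOMES
        if bad:
            raise ValidationError(f"unknown chromosome labels: {sorted(bad)[:5]}")
        for col in ("snp_at_cpg", "snp_at_sbe", "snp_in_probe"):
            if col not in self.table.columns:
                self.table[col] = False
            self.table[col] = self.table[col].fillna(False).astype(bool)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class SampleSheet:
    """Per-sample phenotype table: age, cell_type, plate, study (all optional).

    ``table`` is indexed by sample_id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        if "age" in self.table.columns:
            ages = pd.to_numeric(self.table["age"], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValidationError("negative ages in sample sheet")
            self.table["age"] = ages

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: str | Path) -> str:
    """Auto-detect tab vs comma from the first non-comment line."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    raise ValidationError(f"{path}: empty file")


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0, comment="#")


def read_channel_matrix(
    path_M: str | Path, path_U: str | Path
) -> ChannelMatrix:
    """Load paired M/U intensity tables.

    Probe and sample order is taken from the M file; U is reindexed to match.
    Mismatched index sets raise :class:`AlignmentError` naming offenders.
    """
    m = _read_table(path_M)
    u = _read_table(path_U)
    if set(m.index) != set(u.index):
        raise AlignmentError("probe sets differ: " + _diff_msg(m.index, u.index))
    if set(m.columns) != set(u.columns):
        raise AlignmentError("sample sets differ: " + _diff_msg(m.columns, u.columns))
    u = u.reindex(index=m.index, columns=m.columns)
    return ChannelMatrix(M=m, U=u)


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    return BetaMatrix(values=_read_table(path))


def write_matrix(
    df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write a probes x samples table as TSV, with optional # comment header."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    write_matrix(beta.values, path, header_lines)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    return ProbeAnnotation(table=_read_table(path))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(table=_read_table(path))


def drop_missing(df: pd.DataFrame) -> pd.DataFrame:
    """Drop probes with any missing value, logging the count (opt-in policy)."""
    keep = df.dropna(axis=0)
    n_dropped = len(df) - len(keep)
    if n_dropped:
        logger.warning("dropped %d probes with missing values", n_dropped)
    return keep


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align(
    matrix: BetaMatrix | ChannelMatrix,
    annotation: ProbeAnnotation | None = None,
    sheet: SampleSheet | None = None,
) -> tuple[BetaMatrix | ChannelMatrix, ProbeAnnotation | None, SampleSheet | None]:
    """Intersect probe ids with the annotation and sample ids with the sheet.

    Input order is preserved on the matrix side.  Drop counts on each side are
    logged.  An empty intersection raises :class:`AlignmentError`.  The
    operation is idempotent.
    """
    probe_ids = matrix.probe_ids
    sample_ids = matrix.sample_ids

    if annotation is not None:
        keep_probes = probe_ids[probe_ids.isin(annotation.probe_ids)]
        if len(keep_probes) == 0:
            raise AlignmentError("no probes shared between matrix and annotation")
        _log_drop("probes", "matrix", len(probe_ids) - len(keep_probes))
        _log_drop("probes", "annotation", len(annotation.probe_ids) - len(keep_probes))
        probe_ids = keep_probes
        annotation = ProbeAnnotation(table=annotation.table.loc[probe_ids].copy())

    if sheet is not None:
        keep_samples = sample_ids[sample_ids.isin(sheet.sample_ids)]
        if len(keep_samples) == 0:
            raise AlignmentError("no samples shared between matrix and sample sheet")
        _log_drop("samples", "matrix", len(sample_ids) - len(keep_samples))
        _log_drop("samples", "sheet", len(sheet.sample_ids) - len(keep_samples))
        sample_ids = keep_samples
        sheet = SampleSheet(table=sheet.table.loc[sample_ids].copy())

    if isinstance(matrix, ChannelMatrix):
        matrix = ChannelMatrix(
            M=matrix.M.loc[probe_ids, sample_ids],
            U=matrix.U.loc[probe_ids, sample_ids],
        )
    else:
        matrix = BetaMatrix(values=matrix.values.loc[probe_ids, sample_ids])
    return matrix, annotation, sheet


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique()
        raise ValidationError(f"duplicate {what}: {list(dups[:5])}")


def _diff_msg(a: pd.Index, b: pd.Index) -> str:
    only_a = list(pd.Index(a).difference(b)[:5])
    only_b = list(pd.Index(b).difference(a)[:5])
    return f"only in first: {only_a}; only in second: {only_b}"


def _log_drop(what: str, side: str, n: int) -> None:
    if n:
        logger.info("align: dropped %d %s on the %s side", n, what, side)
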