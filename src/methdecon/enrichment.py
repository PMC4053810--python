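"""Gene-set over-representation for CpG lists by observed/expected ratios.

CpGs — not genes — are the counting unit: for each gene set, the observed
count is the number of query CpGs that map to a gene in the set, the expected
count is the query size scaled by the set's share of the mapped background,
and the ratio observed/expected is reported with a one-sided hypergeometric
p value.  A CpG mapping to several genes contributes to a set at most once.
Gene sets load from plain TSV (set_id, gene_id) plus optional metadata, or
from GMT; no ontology database is bundled, so GO, KEGG or synthetic sets are
interchangeable.  Pairing this with the composition filter gives the
before/after comparison of enrichment ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diagnostics import (
    COMPOSITION_P_CUT,
    COMPOSITION_RANGE_CUT,
    composition_filter,
)
from .matrix_io import ProbeAnnotation, ValidationError

logger = logging.getLogger("methdecon")

MIN_SET_GENES = 25


@dataclass
class GeneSetCollection:
    """Named gene sets: mapping set_id -> set of member gene ids.

    ``meta`` optionally carries set_name and ontology labels per set id.
    """

    sets: dict[str, frozenset[str]]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sets = {sid: frozenset(genes) for sid, genes in self.sets.items()}

    @classmethod
    def from_tsv(
        cls, path: str | Path, meta_path: str | Path | None = None
    ) -> "GeneSetCollection":
        """Two-column TSV: set_id, gene_id (header required)."""
        tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        sid, gid = tab.columns[:2]
        sets = {
            str(s): frozenset(g[gid].astype(str))
            for s, g in tab.groupby(sid, sort=False)
        }
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
        return cls(sets=sets, meta=meta)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = frozenset(g for g in parts[2:] if g)
                names[parts[0]] = parts[1]
        meta = pd.DataFrame({"set_name": names})
        meta.index.name = "set_id"
        return cls(sets=sets, meta=meta)


def map_cpgs_to_genes(
    cpg_ids: Sequence[str] | pd.Index, annotation: ProbeAnnotation
) -> tuple[pd.DataFrame, int]:
    """Map CpGs to gene ids via the annotation's ``gene_id`` column.

    Several gene ids per probe may be given separated by ``;``.  Returns the
    (cpg_id, gene_id) pair table and the count of CpGs with no gene.
    """
    if "gene_id" not in annotation.table.columns:
        raise ValidationError("annotation lacks a 'gene_id' column")
    cpg_ids = pd.Index(cpg_ids)
    genes = annotation.table["gene_id"].reindex(cpg_ids)
    pairs = []
    n_unmapped = 0
    for cpg, g in genes.items():
        if pd.isna(g) or str(g).strip() == "":
            n_unmapped += 1
            continue
        for gid in str(g).split(";"):
            gid = gid.strip()
            if gid:
                pairs.append((cpg, gid))
    out = pd.DataFrame(pairs, columns=["cpg_id", "gene_id"])
    return out, n_unmapped


def obs_exp_enrichment(
    query: Sequence[str] | pd.Index,
    background_map: pd.DataFrame,
    sets: GeneSetCollection,
    min_set_genes: int = MIN_SET_GENES,
) -> pd.DataFrame:
    """Observed/expected CpG-count enrichment per gene set.

    ``background_map`` is the (cpg_id, gene_id) table for the full array
    background; the query must be a subset of the background CpGs.  Only sets
    with at least ``min_set_genes`` genes annotated in the background are
    evaluated.  For each set: observed = query CpGs mapping into the set,
    expected = |query mapped| x (background CpGs in set / |background mapped|),
    p = one-sided hypergeometric tail P(X >= observed).  Rows are ranked by p.
    """
    query = pd.Index(pd.unique(pd.Index(query)))
    bg_cpgs = pd.Index(pd.unique(background_map["cpg_id"]))
    outside = query[~query.isin(bg_cpgs)]
    if len(outside):
        raise ValidationError(
            f"{len(outside)} query CpGs absent from background, "
            f"e.g. {list(outside[:5])}"
        )
    gene_to_cpgs = background_map.groupby("gene_id")["cpg_id"].agg(set)
    bg_genes = frozenset(gene_to_cpgs.index)
    n_bg = len(bg_cpgs)
    query_set = set(query)
    cpg_mapped = set(background_map["cpg_id"])
    query_mapped = query_set & cpg_mapped
    n_query = len(query_mapped)

    rows = []
    for sid, genes in sets.sets.items():
        annotated = genes & bg_genes
        if len(annotated) < min_set_genes:
            continue
        set_cpgs: set[str] = set()
        for g in annotated:
            set_cpgs |= gene_to_cpgs[g]
        n_set = len(set_cpgs)
        observed = len(query_mapped & set_cpgs)
        expected = n_query * n_set / n_bg
        ratio = observed / expected if expected > 0 else np.nan
        p = float(hypergeom.sf(observed - 1, n_bg, n_set, n_query))
        rows.append(
            {
                "set_id": sid,
                "set_size_genes": len(annotated),
                "set_size_cpgs": n_set,
                "observed": observed,
                "expected": expected,
                "ratio": ratio,
                "p": p,
            }
        )
    if not rows:
        raise ValidationError(
            f"no gene set has >= {min_set_genes} annotated genes in the background"
        )
    out = pd.DataFrame(rows).set_index("set_id")
    out = out.sort_values(["p", "set_id"], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    if sets.meta is not None:
        out = out.join(sets.meta, how="left")
    return out


def before_after_comparison(
    query: Sequence[str] | pd.Index,
    comp_stats: pd.DataFrame,
    background_map: pd.DataFrame,
    sets: GeneSetCollection,
    p_cut: float = COMPOSITION_P_CUT,
    range_cut: float = COMPOSITION_RANGE_CUT,
    min_set_genes: int = MIN_SET_GENES,
    strict_filter: bool = False,
) -> pd.DataFrame:
    """Enrichment before vs after removing composition-associated CpGs.

    Runs :func:`obs_exp_enrichment` on the raw query and again after the
    composition filter (F-test p < ``p_cut`` AND beta range > ``range_cut``),
    and reports per set the counts, ratios and p-value ranks in both
    conditions plus the rank shift (positive = the set rose after filtering).
    """
    before = obs_exp_enrichment(query, background_map, sets, min_set_genes)
    retained, _ = composition_filter(
        query, comp_stats, p_cut=p_cut, range_cut=range_cut, strict=strict_filter
    )
    if len(retained) == 0:
        raise ValidationError(
            "composition filter removed every query CpG; nothing to enrich"
        )
    after = obs_exp_enrichment(retained, background_map, sets, min_set_genes)
    merged = before.add_suffix("_before").join(
        after.add_suffix("_after"), how="outer"
    )
    merged["rank_shift"] = merged["rank_before"] - merged["rank_after"]
    logger.info(
        "before/after enrichment: %d -> %d query CpGs after composition filter",
        len(pd.Index(query)),
        len(retained),
    )
    return merged
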