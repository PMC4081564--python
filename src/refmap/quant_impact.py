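"""Downstream quantification impact: gene counts, reductions, fold changes.

Gene-level read counting follows the intersection-strict convention: a read
is assigned to gene G only if every aligned block lies entirely within the
exons of at least one transcript of G, and G is the only gene satisfying
that -- reads straddling an exon-intron boundary or ambiguous between genes
are discarded.  A ``union`` mode (any exonic overlap, still unambiguous) is
available for comparison.

On top of the counts this module derives the two headline impact products:
the list of genes whose counts drop by at least a threshold percentage when
the annotation is withheld, and the concordance of between-sample log2 fold
changes computed from counts under the two runs, with discordance flags at
|delta log2FC| > 2 ("blue") and > 3.3 ("red").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AlignmentRecord, Annotation
from .compare_engine import profile_from_record

__all__ = [
    "ImpactTable",
    "count_genes",
    "count_table",
    "reduction_report",
    "fc_concordance",
]

COUNT_MODES = ("intersection-strict", "union")

FLAG_NONE = "none"
FLAG_BLUE = "blue"
FLAG_RED = "red"


def count_genes(
    records: Iterable[AlignmentRecord],
    annotation: Annotation,
    mode: str = "intersection-strict",
) -> dict[str, int]:
    """Gene -> read count for unique-mode alignment records.

    Secondary and unmapped records are skipped.  ``intersection-strict``
    requires every block of the read to be contained in exons of one
    transcript of the gene; ``union`` requires any block to overlap the
    gene's exons.  In both modes a read ambiguous between two genes is
    counted for neither.
    """
    if mode not in COUNT_MODES:
        raise ValueError(f"mode must be one of {COUNT_MODES}, got {mode!r}")
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.mapped or rec.secondary:
            continue
        profile = profile_from_record(rec)
        span = (profile.blocks[0][0], profile.blocks[-1][1])
        candidates = annotation.genes_overlapping(rec.chrom, span[0], span[1])
        hits: list[str] = []
        for gene in candidates:
            if mode == "union":
                if _any_block_overlaps(profile.blocks, annotation, gene, rec.chrom):
                    hits.append(gene)
            else:
                if _fully_exonic(profile.blocks, annotation, gene, rec.chrom):
                    hits.append(gene)
        if len(hits) == 1:
            counts[hits[0]] = counts.get(hits[0], 0) + 1
    return counts


def _any_block_overlaps(blocks, annotation: Annotation, gene: str, chrom: str) -> bool:
    for s, e in blocks:
        for model in annotation.transcripts_of(gene):
            if model.chrom != chrom:
                continue
            for ex in model.exons:
                if s < ex.end and ex.start < e:
                    return True
    return False


def _fully_exonic(blocks, annotation: Annotation, gene: str, chrom: str) -> bool:
    for model in annotation.transcripts_of(gene):
        if model.chrom != chrom:
            continue
        if all(
            any(ex.start <= s and e <= ex.end for ex in model.exons)
            for s, e in blocks
        ):
            return True
    return False


def count_table(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene counts under both runs with the percent reduction.

    ``reduction_pct = 100 * (count_A - count_B) / count_A`` where
    ``count_A > 0``; genes never counted in run A get an empty reduction.
    """
    if genes is None:
        genes = sorted(set(counts_a) | set(counts_b))
    rows = []
    for g in genes:
        a = counts_a.get(g, 0)
        b = counts_b.get(g, 0)
        reduction = 100.0 * (a - b) / a if a > 0 else np.nan
        rows.append(dict(gene=g, count_A=a, count_B=b, reduction_pct=reduction))
    return pd.DataFrame(rows, columns=["gene", "count_A", "count_B", "reduction_pct"])


def reduction_report(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    threshold_pct: float = 20.0,
) -> pd.DataFrame:
    """Genes whose count drops by at least ``threshold_pct`` without annotation.

    Only genes with ``count_A > 0`` enter the denominator; output is sorted
    by reduction, largest first.
    """
    table = count_table(counts_a, counts_b)
    table = table[table["count_A"] > 0]
    table = table[table["reduction_pct"] >= threshold_pct]
    return table.sort_values(
        ["reduction_pct", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def _normalize_pair(
    c1: Mapping[str, int], c2: Mapping[str, int], genes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Scale two samples' counts to equal library totals (their mean)."""
    v1 = np.array([c1.get(g, 0) for g in genes], dtype=float)
    v2 = np.array([c2.get(g, 0) for g in genes], dtype=float)
    t1, t2 = v1.sum(), v2.sum()
    if t1 > 0 and t2 > 0:
        target = (t1 + t2) / 2.0
        v1 *= target / t1
        v2 *= target / t2
    return v1, v2


def fc_concordance(
    counts_s1_a: Mapping[str, int],
    counts_s2_a: Mapping[str, int],
    counts_s1_b: Mapping[str, int],
    counts_s2_b: Mapping[str, int],
    pseudocount: float = 0.5,
    thresholds: tuple[float, float] = (2.0, 3.3),
) -> pd.DataFrame:
    """Between-sample log2 fold changes under both runs, with flags.

    For each run X, counts are library-size normalized (scaled to equal
    totals) and ``log2fc_X = log2((n_s1 + p) / (n_s2 + p))``.  ``delta`` is
    the absolute difference between the two runs' fold changes; flags are
    strict: blue above ``thresholds[0]``, red above ``thresholds[1]``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    blue_thr, red_thr = thresholds
    if red_thr < blue_thr:
        raise ValueError("red threshold must be >= blue threshold")
    genes = sorted(
        set(counts_s1_a) | set(counts_s2_a) | set(counts_s1_b) | set(counts_s2_b)
    )
    a1, a2 = _normalize_pair(counts_s1_a, counts_s2_a, genes)
    b1, b2 = _normalize_pair(counts_s1_b, counts_s2_b, genes)
    log2fc_a = np.log2((a1 + pseudocount) / (a2 + pseudocount))
    log2fc_b = np.log2((b1 + pseudocount) / (b2 + pseudocount))
    delta = np.abs(log2fc_a - log2fc_b)
    flags = np.where(delta > red_thr, FLAG_RED, np.where(delta > blue_thr, FLAG_BLUE, FLAG_NONE))
    return pd.DataFrame(
        dict(
            gene=genes,
            log2fc_A=log2fc_a,
            log2fc_B=log2fc_b,
            delta=delta,
            flag=flags,
        )
    )


@dataclass
class ImpactTable:
    """Bundle of the quantification-impact products for one comparison."""

    counts: pd.DataFrame
    reduced: pd.DataFrame
    concordance: pd.DataFrame | None = None


def build_impact_table(
    records_a: Iterable[AlignmentRecord],
    records_b: Iterable[AlignmentRecord],
    annotation: Annotation,
    mode: str = "intersection-strict",
    threshold_pct: float = 20.0,
) -> ImpactTable:
    """Count both runs over the annotation and derive the reduction list."""
    counts_a = count_genes(records_a, annotation, mode=mode)
    counts_b = count_genes(records_b, annotation, mode=mode)
    genes = sorted(annotation.genes)
    return ImpactTable(
        counts=count_table(counts_a, counts_b, genes=genes),
        reduced=reduction_report(counts_a, counts_b, threshold_pct=threshold_pct),
    )
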