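"""Per-read comparison of a guided and an annotation-free alignment run.

Every read mapped in run A (the annotation-guided run) is assigned one of
three fates in run B (the annotation-free run):

* ``Identical``   -- same chromosome, strand and exact block list;
* ``Alternative`` -- still mapped, but to a different region, strand or
  splice configuration;
* ``Unmapped``    -- lost entirely without the annotation.

Junction status, exon span and the MOE statistic (minimum overlap with an
exon, ``min(OL, OR)`` -- the shorter flanking block of a junction
alignment) are always taken from the run-A profile, so the categories
describe what happens to reads the guided aligner considered well placed.
MOE histograms are restricted to two-block profiles, where the statistic
has its clean interpretation; for a read of length L it ranges from 1 to
``floor(L / 2)``.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import AlignmentRecord, read_sam

__all__ = [
    "Category",
    "JunctionProfile",
    "ComparisonRecord",
    "CategorySummary",
    "PairingError",
    "profile_from_cigar",
    "profile_from_record",
    "classify",
    "pair_records",
    "pair_runs",
    "summarize",
    "comparison_table",
]

logger = logging.getLogger(__name__)


class Category(str, Enum):
    IDENTICAL = "Identical"
    ALTERNATIVE = "Alternative"
    UNMAPPED = "Unmapped"


CATEGORIES = (Category.IDENTICAL, Category.ALTERNATIVE, Category.UNMAPPED)


class PairingError(ValueError):
    """Records passed to classify/pairing do not belong together."""


@dataclass(frozen=True)
class JunctionProfile:
    """Block/intron decomposition of one alignment.

    ``blocks`` are the genomic M-runs (D extends a block, I/S only consume
    read bases, N opens a new block after the gap).  ``exon_span`` is the
    block count and a read is a junction read iff it spans at least two
    blocks.
    """

    blocks: tuple[tuple[int, int], ...]
    introns: tuple[int, ...]
    chrom: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("profile must have at least one block")
        if len(self.introns) != len(self.blocks) - 1:
            raise ValueError("intron count must be block count minus one")
        for (s, e) in self.blocks:
            if e <= s:
                raise ValueError(f"empty block [{s},{e})")

    @property
    def exon_span(self) -> int:
        return len(self.blocks)

    @property
    def is_junction(self) -> bool:
        return len(self.blocks) >= 2

    @property
    def moe(self) -> int | None:
        """min(first block length, last block length); junction reads only."""
        if not self.is_junction:
            return None
        first = self.blocks[0][1] - self.blocks[0][0]
        last = self.blocks[-1][1] - self.blocks[-1][0]
        return min(first, last)


def profile_from_cigar(
    pos: int,
    cigar: Sequence[tuple[str, int]],
    chrom: str | None = None,
    strand: str | None = None,
) -> JunctionProfile:
    """Decompose a CIGAR over {M, I, D, N, S} into genomic blocks.

    A CIGAR whose first or last element is N (a dangling intron) is
    rejected, as are unknown operations.
    """
    if not cigar:
        raise ValueError("empty CIGAR")
    ops = [op for op, _ in cigar]
    for op, ln in cigar:
        if op not in "MIDNS":
            raise ValueError(f"unsupported CIGAR op {op!r}")
        if ln <= 0:
            raise ValueError(f"non-positive CIGAR length {op}{ln}")
    if ops[0] == "N" or ops[-1] == "N":
        raise ValueError("CIGAR must not start or end with an N gap")
    blocks: list[tuple[int, int]] = []
    introns: list[int] = []
    block_start = pos
    cur = pos
    for op, ln in cigar:
        if op in "MD":
            cur += ln
        elif op == "N":
            if cur == block_start:
                raise ValueError("N gap with no preceding aligned block")
            blocks.append((block_start, cur))
            introns.append(ln)
            cur += ln
            block_start = cur
        # I and S consume read bases only
    if cur == block_start:
        raise ValueError("CIGAR has no reference-consuming operation")
    blocks.append((block_start, cur))
    return JunctionProfile(tuple(blocks), tuple(introns), chrom=chrom, strand=strand)


def profile_from_record(rec: AlignmentRecord) -> JunctionProfile:
    if not rec.mapped:
        raise ValueError(f"record {rec.read_id!r} is unmapped")
    return profile_from_cigar(rec.pos, rec.cigar, chrom=rec.chrom, strand=rec.strand)


@dataclass(frozen=True)
class ComparisonRecord:
    read_id: str
    category: Category
    profile_a: JunctionProfile
    profile_b: JunctionProfile | None

    def __post_init__(self) -> None:
        if (self.category is Category.UNMAPPED) != (self.profile_b is None):
            raise ValueError("profile_b must be absent exactly when Unmapped")


def classify(
    rec_a: AlignmentRecord,
    rec_b: AlignmentRecord,
    strand_matters: bool = True,
) -> ComparisonRecord:
    """Compare one read's guided (A) and annotation-free (B) placements.

    Defined only for reads mapped in run A.  Identity means equal
    chromosome, strand (unless ``strand_matters`` is off) and ordered block
    list; mismatch counts and tags are deliberately ignored -- the
    comparison is about placement and splice sites, not scores.
    """
    if rec_a.read_id != rec_b.read_id:
        raise PairingError(
            f"read ids differ: {rec_a.read_id!r} vs {rec_b.read_id!r}"
        )
    if not rec_a.mapped:
        raise ValueError(
            f"read {rec_a.read_id!r} is unmapped in run A; comparison is "
            "defined on A-mapped reads only"
        )
    profile_a = profile_from_record(rec_a)
    if not rec_b.mapped:
        return ComparisonRecord(rec_a.read_id, Category.UNMAPPED, profile_a, None)
    profile_b = profile_from_record(rec_b)
    same = (
        profile_a.chrom == profile_b.chrom
        and profile_a.blocks == profile_b.blocks
        and (not strand_matters or profile_a.strand == profile_b.strand)
    )
    category = Category.IDENTICAL if same else Category.ALTERNATIVE
    return ComparisonRecord(rec_a.read_id, category, profile_a, profile_b)


def _primary_by_read(
    records: Iterable[AlignmentRecord], run_name: str
) -> dict[str, AlignmentRecord]:
    out: dict[str, AlignmentRecord] = {}
    for rec in records:
        if rec.secondary:
            continue
        if rec.read_id in out:
            raise ValueError(
                f"duplicate primary record for read {rec.read_id!r} in {run_name}; "
                "pairing expects unique-mode input"
            )
        out[rec.read_id] = rec
    return out


def pair_records(
    records_a: Iterable[AlignmentRecord],
    records_b: Iterable[AlignmentRecord],
    strand_matters: bool = True,
) -> list[ComparisonRecord]:
    """Name-match two unique-mode runs and classify every A-mapped read.

    Reads unmapped in A are counted (logged) but never categorized; reads
    present only in B are logged and ignored -- the category partition is
    over the A-mapped set.
    """
    by_a = _primary_by_read(records_a, "run A")
    by_b = _primary_by_read(records_b, "run B")
    out: list[ComparisonRecord] = []
    a_unmapped = 0
    for read_id, rec_a in by_a.items():
        if not rec_a.mapped:
            a_unmapped += 1
            continue
        rec_b = by_b.get(read_id)
        if rec_b is None:
            rec_b = AlignmentRecord(read_id=read_id, mapped=False)
        out.append(classify(rec_a, rec_b, strand_matters=strand_matters))
    b_only = len(set(by_b) - set(by_a))
    if a_unmapped:
        logger.info("%d reads unmapped in run A were not categorized", a_unmapped)
    if b_only:
        logger.info("%d reads present only in run B were ignored", b_only)
    if by_a and by_b and not set(by_a) & set(by_b):
        logger.warning("no read ids are shared between the two runs")
    return out


def pair_runs(
    sam_a: str | Path,
    sam_b: str | Path,
    strand_matters: bool = True,
) -> list[ComparisonRecord]:
    """File-level wrapper around :func:`pair_records` for two SAM paths."""
    return pair_records(
        read_sam(sam_a), read_sam(sam_b), strand_matters=strand_matters
    )


@dataclass
class CategorySummary:
    """All per-category statistics derived from one comparison run."""

    total: int
    counts: dict[Category, int]
    percentages: dict[Category, float]
    junction_total: int
    junction_counts: dict[Category, int]
    junction_percentages: dict[Category, float]
    junction_fraction: dict[Category, float]
    overall_junction_fraction: float
    exon_span_matrix: pd.DataFrame
    moe_histograms: dict[Category, Counter]

    def category_table(self) -> pd.DataFrame:
        """Category counts and percentages, all reads and junction reads."""
        rows = []
        for cat in CATEGORIES:
            rows.append(
                dict(
                    category=cat.value,
                    reads=self.counts[cat],
                    pct=self.percentages[cat],
                    junction_reads=self.junction_counts[cat],
                    junction_pct=self.junction_percentages[cat],
                    junction_fraction_pct=100.0 * self.junction_fraction[cat],
                )
            )
        return pd.DataFrame(rows)

    def moe_table(self) -> pd.DataFrame:
        """Long-format MOE histogram (two-block junction reads only)."""
        rows = []
        for cat in CATEGORIES:
            for moe in sorted(self.moe_histograms[cat]):
                rows.append(
                    dict(category=cat.value, moe=moe, reads=self.moe_histograms[cat][moe])
                )
        return pd.DataFrame(rows, columns=["category", "moe", "reads"])


def summarize(records: Sequence[ComparisonRecord]) -> CategorySummary:
    """Aggregate comparison records into the four statistics families.

    Junction status, exon span and MOE are read from the run-A profile.
    Percentages are over the A-mapped total (all categories) and over the
    A-mapped junction total (junction block).  Raises on empty input.
    """
    if not records:
        raise ValueError("summarize requires at least one comparison record")
    counts = {cat: 0 for cat in CATEGORIES}
    junction_counts = {cat: 0 for cat in CATEGORIES}
    span_counter: dict[Category, Counter] = {cat: Counter() for cat in CATEGORIES}
    moe_hist: dict[Category, Counter] = {cat: Counter() for cat in CATEGORIES}
    for rec in records:
        prof = rec.profile_a
        counts[rec.category] += 1
        span_counter[rec.category][prof.exon_span] += 1
        if prof.is_junction:
            junction_counts[rec.category] += 1
            if prof.exon_span == 2:
                moe_hist[rec.category][prof.moe] += 1
    total = len(records)
    junction_total = sum(junction_counts.values())
    percentages = {cat: 100.0 * counts[cat] / total for cat in CATEGORIES}
    junction_percentages = {
        cat: (100.0 * junction_counts[cat] / junction_total) if junction_total else 0.0
        for cat in CATEGORIES
    }
    junction_fraction = {
        cat: (junction_counts[cat] / counts[cat]) if counts[cat] else 0.0
        for cat in CATEGORIES
    }
    spans = sorted({s for c in span_counter.values() for s in c})
    matrix = pd.DataFrame(
        [[span_counter[cat][s] for s in spans] for cat in CATEGORIES],
        index=[cat.value for cat in CATEGORIES],
        columns=spans,
    )
    return CategorySummary(
        total=total,
        counts=counts,
        percentages=percentages,
        junction_total=junction_total,
        junction_counts=junction_counts,
        junction_percentages=junction_percentages,
        junction_fraction=junction_fraction,
        overall_junction_fraction=junction_total / total,
        exon_span_matrix=matrix,
        moe_histograms=moe_hist,
    )


def comparison_table(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """Per-read TSV-ready table of the comparison outcome."""

    def fmt_blocks(profile: JunctionProfile | None) -> str:
        if profile is None:
            return ""
        return ";".join(f"{s}-{e}" for s, e in profile.blocks)

    rows = []
    for rec in records:
        rows.append(
            dict(
                read_id=rec.read_id,
                category=rec.category.value,
                chrom_a=rec.profile_a.chrom or "",
                blocks_a=fmt_blocks(rec.profile_a),
                chrom_b=(rec.profile_b.chrom or "") if rec.profile_b else "",
                blocks_b=fmt_blocks(rec.profile_b),
                exon_span_a=rec.profile_a.exon_span,
                moe_a=rec.profile_a.moe if rec.profile_a.moe is not None else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "category",
            "chrom_a",
            "blocks_a",
            "chrom_b",
            "blocks_b",
            "exon_span_a",
            "moe_a",
        ],
    )
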