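"""Gene models, transcript-to-genome projection, and FASTA/GTF/SAM input-output.

Coordinates are 0-based half-open everywhere inside the package. The 1-based
inclusive conventions of GTF and the 1-based POS of SAM are applied only at
the file boundary, so no other module ever needs to reason about off-by-one
conversions.

The GTF dialect accepted here is the UCSC Table-Browser output: exon feature
lines carrying ``gene_id`` and ``transcript_id`` attributes.  Other feature
types are ignored; structurally broken lines are rejected with the offending
line number.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "Annotation",
    "AlignmentRecord",
    "GtfParseError",
    "ValidationError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "transcript_sequence",
    "project_to_genome",
    "read_sam",
    "write_sam",
]

STRANDS = ("+", "-")

#: CIGAR operations understood by the package.  ``=``/``X`` are normalized to
#: ``M`` on input; anything else is rejected.
CIGAR_OPS = "MIDNS"

_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
_CODE_TO_OP = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 7: "M", 8: "M"}


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open, stranded interval on a reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: ordered, non-overlapping exons on one strand.

    ``exons`` are sorted by genomic start and separated by gaps of at least
    one base (the introns).  The spliced length is the sum of exon lengths;
    transcript coordinates run 5'->3' along the mature transcript, which for
    minus-strand models means *descending* genomic position.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon {ex} disagrees with "
                    f"transcript chrom/strand {self.chrom}/{self.strand}"
                )
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start <= left.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons [{left.start},{left.end}) "
                    f"and [{right.start},{right.end}) overlap or touch"
                )

    @classmethod
    def from_coords(
        cls,
        gene_id: str,
        transcript_id: str,
        chrom: str,
        strand: str,
        coords: Iterable[tuple[int, int]],
    ) -> "TranscriptModel":
        exons = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in sorted(coords)
        )
        return cls(gene_id, transcript_id, chrom, strand, exons)

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


class Annotation:
    """A collection of transcript models with gene and interval lookups."""

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        self._transcripts: dict[str, TranscriptModel] = {}
        genes: dict[str, list[str]] = defaultdict(list)
        trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for t in transcripts:
            if t.transcript_id in self._transcripts:
                raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
            self._transcripts[t.transcript_id] = t
            genes[t.gene_id].append(t.transcript_id)
            for ex in t.exons:
                trees[t.chrom].addi(ex.start, ex.end, (t.gene_id, t.transcript_id))
        self._genes = {g: tuple(tids) for g, tids in genes.items()}
        self._trees = dict(trees)

    @property
    def transcripts(self) -> Mapping[str, TranscriptModel]:
        return self._transcripts

    @property
    def genes(self) -> Mapping[str, tuple[str, ...]]:
        return self._genes

    def transcripts_of(self, gene_id: str) -> tuple[TranscriptModel, ...]:
        return tuple(self._transcripts[tid] for tid in self._genes[gene_id])

    def genes_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        """Gene ids with at least one exon overlapping [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data[0] for iv in tree.overlap(start, end)}

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> Annotation:
    """Parse a UCSC-dialect GTF into an :class:`Annotation`.

    Only ``exon`` feature lines are used; 1-based inclusive coordinates are
    converted to 0-based half-open.  Malformed lines raise
    :class:`GtfParseError` naming the line number; structurally invalid
    transcripts (e.g. overlapping exons) raise :class:`ValidationError`.
    """
    per_tx: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            chrom = fields[0]
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(
                    f"line {lineno}: bad coordinate range {start1}-{end1}"
                )
            strand = fields[6]
            if strand not in STRANDS:
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: missing gene_id/transcript_id attribute"
                )
            tid = attrs["transcript_id"]
            prev = meta.get(tid)
            if prev is not None and prev != (attrs["gene_id"], chrom, strand):
                raise GtfParseError(
                    f"line {lineno}: transcript {tid!r} changes gene/chrom/strand"
                )
            meta[tid] = (attrs["gene_id"], chrom, strand)
            per_tx[tid].append((start1 - 1, end1))
    models = []
    for tid, coords in per_tx.items():
        gene_id, chrom, strand = meta[tid]
        models.append(TranscriptModel.from_coords(gene_id, tid, chrom, strand, coords))
    return Annotation(models)


def write_gtf(annotation: Annotation, path: str | Path, source: str = "refmap") -> None:
    """Write exon feature lines in the same UCSC dialect ``read_gtf`` accepts."""
    with open(path, "w") as fh:
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            for ex in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Transcript sequence and projection


def transcript_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """The mature (spliced) transcript sequence, 5'->3'.

    Exon substrings are concatenated in genomic order and the result is
    reverse-complemented as a whole for minus-strand models.
    """
    try:
        chrom_seq = genome[model.chrom]
    except KeyError as exc:
        raise ValidationError(f"unknown chromosome {model.chrom!r}") from exc
    for ex in model.exons:
        if ex.end > len(chrom_seq):
            raise ValidationError(
                f"exon [{ex.start},{ex.end}) outside {model.chrom} "
                f"(length {len(chrom_seq)})"
            )
    spliced = "".join(chrom_seq[ex.start : ex.end] for ex in model.exons)
    if model.strand == "-":
        spliced = reverse_complement(spliced)
    return spliced


def project_to_genome(
    model: TranscriptModel, t_start: int, length: int
) -> tuple[int, str, tuple[tuple[str, int], ...]]:
    """Project a transcript-coordinate window onto the genome.

    Returns ``(pos, strand, cigar)`` where ``pos`` is the leftmost genomic
    offset and the CIGAR uses ``M`` blocks for exonic stretches and ``N``
    gaps for skipped introns, in ascending genomic order (the SAM
    convention, also for minus-strand models).
    """
    splen = model.spliced_length
    if length <= 0:
        raise ValueError(f"window length must be positive, got {length}")
    if t_start < 0 or t_start + length > splen:
        raise ValueError(
            f"window [{t_start}, {t_start + length}) outside spliced "
            f"length {splen} of {model.transcript_id}"
        )
    # Transcript offset 0 is the genomic 5' end: leftmost base for '+',
    # rightmost base for '-'.  Convert to a forward-splice window first.
    if model.strand == "-":
        fs = splen - (t_start + length)
    else:
        fs = t_start
    fe = fs + length
    blocks: list[tuple[int, int]] = []
    off = 0
    for ex in model.exons:
        elen = len(ex)
        lo = max(fs, off)
        hi = min(fe, off + elen)
        if lo < hi:
            blocks.append((ex.start + lo - off, ex.start + hi - off))
        off += elen
    cigar: list[tuple[str, int]] = []
    for i, (bs, be) in enumerate(blocks):
        if i:
            cigar.append(("N", bs - blocks[i - 1][1]))
        cigar.append(("M", be - bs))
    return blocks[0][0], model.strand, tuple(cigar)


# ---------------------------------------------------------------------------
# Alignment records and SAM


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's placement (or its absence).

    ``n_locations`` counts the equally-best distinct placements the aligner
    saw: 1 for a clean unique hit, >1 for a read dropped (unique mode) or
    reported multiply (multiple mode), 0 for no candidate at all.
    ``secondary`` marks the extra records of a multiple-mode report.
    """

    read_id: str
    mapped: bool
    chrom: str | None = None
    pos: int | None = None
    strand: str | None = None
    cigar: tuple[tuple[str, int], ...] | None = None
    nm: int | None = None
    n_locations: int | None = None
    secondary: bool = False

    def __post_init__(self) -> None:
        placement = (self.chrom, self.pos, self.strand, self.cigar)
        if self.mapped:
            if any(v is None for v in placement):
                raise ValidationError(
                    f"mapped record {self.read_id!r} is missing placement fields"
                )
            if self.strand not in STRANDS:
                raise ValidationError(f"bad strand {self.strand!r}")
            for op, ln in self.cigar:  # type: ignore[union-attr]
                if op not in CIGAR_OPS or ln <= 0:
                    raise ValidationError(f"bad CIGAR element {op}{ln}")
        else:
            if any(v is not None for v in placement):
                raise ValidationError(
                    f"unmapped record {self.read_id!r} carries placement fields"
                )


def write_sam(
    records: Iterable[AlignmentRecord],
    refs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Serialize records to a plain-text SAM file with @SQ headers.

    POS is 1-based in the file; flag 4 marks unmapped, 16 minus-strand and
    256 secondary records.  NM and NH optional tags carry the mismatch count
    and the number of equally-best placements.
    """
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in refs.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            flag = 0
            if not rec.mapped:
                flag |= 4
            else:
                if rec.chrom not in refs:
                    raise ValidationError(
                        f"record {rec.read_id!r} references unknown chrom {rec.chrom!r}"
                    )
                if rec.strand == "-":
                    flag |= 16
                if rec.secondary:
                    flag |= 256
                seg.reference_name = rec.chrom
                seg.reference_start = rec.pos
                seg.cigartuples = [(_OP_TO_CODE[op], ln) for op, ln in rec.cigar]
                seg.mapping_quality = 255
            seg.flag = flag
            tags = []
            if rec.nm is not None:
                tags.append(("NM", rec.nm))
            if rec.n_locations is not None:
                tags.append(("NH", rec.n_locations))
            seg.set_tags(tags)
            out.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a SAM file back into :class:`AlignmentRecord` objects.

    ``=``/``X`` CIGAR operations are normalized to ``M``; adjacent equal
    operations are merged so the round trip is insensitive to run splitting.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            nm = seg.get_tag("NM") if seg.has_tag("NM") else None
            nh = seg.get_tag("NH") if seg.has_tag("NH") else None
            if seg.is_unmapped:
                records.append(
                    AlignmentRecord(
                        read_id=seg.query_name,
                        mapped=False,
                        nm=nm,
                        n_locations=nh,
                    )
                )
                continue
            cigar: list[tuple[str, int]] = []
            for code, ln in seg.cigartuples:
                op = _CODE_TO_OP.get(code)
                if op is None:
                    raise ValidationError(
                        f"unsupported CIGAR op code {code} in {seg.query_name!r}"
                    )
                if cigar and cigar[-1][0] == op:
                    cigar[-1] = (op, cigar[-1][1] + ln)
                else:
                    cigar.append((op, ln))
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    mapped=True,
                    chrom=seg.reference_name,
                    pos=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=tuple(cigar),
                    nm=nm,
                    n_locations=nh,
                    secondary=seg.is_secondary,
                )
            )
    return records
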