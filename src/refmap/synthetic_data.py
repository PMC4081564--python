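"""Synthetic genome, annotation and read generation with mapping confounders.

The generator builds a random genome carrying the structural features that
make spliced short-read mapping hard, so every downstream stage of the
package can be exercised with full ground truth and no external downloads:

* multi-exon genes (2-8 exons) with exons that are frequently shorter than
  the read length;
* an optional *retrotransposed pseudogene*: an intronless, lightly mutated
  copy of one gene's mature transcript inserted intergenically and kept out
  of the annotation -- the classic sink for misplaced junction reads;
* an optional byte-identical *paralog* copy of one gene's whole locus, both
  copies annotated -- the classic multi-mapping trap;
* an optional gene with a tiny internal exon (default 6 bp), which no
  de-novo splice search can anchor.

Reads are 75 bp single-end by default, sampled uniformly per base across
transcripts, in the orientation of their transcript, with independent
per-base substitution errors and constant base quality.  Every read carries
a :class:`ReadTruth` record.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .annotation_io import Annotation, TranscriptModel, project_to_genome, transcript_sequence

__all__ = [
    "SimConfig",
    "SimRead",
    "ReadTruth",
    "stage_rng",
    "make_genome",
    "simulate_reads",
    "write_fastq",
    "write_truth",
    "truth_table",
]

BASES = "ACGT"


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """An independent random substream for one pipeline stage.

    The stage name is hashed into the seed entropy so that, e.g., drawing
    more reads never perturbs the genome, and two samples simulated from the
    same genome use unrelated streams.
    """
    salt = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, salt)))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    ``read_length`` follows the 75 bp single-read regime of short-read bulk
    RNA-seq; ``small_exon_length`` defaults to the 6 bp internal exon that
    defeats anchor-based splice discovery.  ``error_rate`` is a per-base
    substitution probability (no indels).  ``retrocopy_mutations`` is the
    total substitution count planted in the pseudogene copy; the default of
    20 over a typical ~1 kb parent transcript gives percent-scale
    divergence, so a 75 bp read window over the retrocopy usually differs
    from the parent mRNA at one or two bases -- the regime in which
    processed pseudogenes capture reads with visible mismatches.
    """

    seed: int = 0
    read_length: int = 75
    n_reads: int = 20000
    error_rate: float = 0.005
    n_genes: int = 30
    exon_length_range: tuple[int, int] = (20, 300)
    small_exon_length: int = 6
    intron_length_range: tuple[int, int] = (60, 1500)
    retrocopy_mutations: int = 20
    include_retrocopies: bool = True
    include_identical_paralog: bool = True
    include_small_exon_gene: bool = True

    def __post_init__(self) -> None:
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_reads < 0 or self.n_genes < 1:
            raise ValueError("n_reads must be >= 0 and n_genes >= 1")
        if self.exon_length_range[0] < 1 or self.intron_length_range[0] < 1:
            raise ValueError("exon/intron minimum lengths must be >= 1")
        if self.exon_length_range[0] > self.exon_length_range[1]:
            raise ValueError("exon_length_range min exceeds max")
        if self.intron_length_range[0] > self.intron_length_range[1]:
            raise ValueError("intron_length_range min exceeds max")
        if self.small_exon_length < 1:
            raise ValueError("small_exon_length must be >= 1")
        if self.retrocopy_mutations < 0:
            raise ValueError("retrocopy_mutations must be >= 0")
        n_special = sum(
            (
                self.include_retrocopies,
                self.include_identical_paralog,
                self.include_small_exon_gene,
            )
        )
        if self.n_genes < max(n_special, 1) + 1:
            raise ValueError(
                f"n_genes={self.n_genes} is too small for the requested special "
                f"gene content ({n_special} special roles)"
            )


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    transcript_id: str
    t_start: int
    n_errors: int
    true_exon_span: int

    def __post_init__(self) -> None:
        if self.true_exon_span < 1:
            raise ValueError("true_exon_span must be >= 1")

    @property
    def spans_junction(self) -> bool:
        return self.true_exon_span >= 2


def make_genome(
    config: SimConfig,
) -> tuple[dict[str, str], Annotation, pd.DataFrame]:
    """Build the synthetic genome, its annotation and a provenance table.

    The provenance table records every planted element -- ordinary genes,
    the identical paralog copy, and the (unannotated) retrocopy with its
    mutation count -- so tests and reports can locate them without parsing
    the annotation.  Deterministic given ``config.seed``.
    """
    rng = stage_rng(config.seed, "genome")
    chrom = "chr1"
    exon_lo, exon_hi = config.exon_length_range
    intron_lo, intron_hi = config.intron_length_range
    L = config.read_length

    # Assign the special roles to fixed gene indices so provenance is stable.
    small_exon_idx = 0 if config.include_small_exon_gene else -1
    paralog_idx = 1 if config.include_identical_paralog else -1

    parts: list[str] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []
    prov_rows: list[dict] = []

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    def spacer() -> None:
        emit(_random_seq(rng, int(rng.integers(300, 801))))

    paralog_locus: tuple[str, list[tuple[int, int]], str, str] | None = None
    mrnas: dict[str, str] = {}  # gene_id -> mature transcript sequence

    for i in range(config.n_genes):
        gid = f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if i == small_exon_idx:
            # Modelled on cardiac-troponin-like genes: a run of short
            # internal exons around the tiny one, so single reads can span
            # three or more exons.
            exon_lens = [
                int(rng.integers(120, 201)),
                30,
                config.small_exon_length,
                30,
                int(rng.integers(120, 201)),
            ]
        else:
            n_exons = int(rng.integers(2, 9))
            exon_lens = [int(x) for x in rng.integers(exon_lo, exon_hi + 1, n_exons)]
        deficit = (L + 5) - sum(exon_lens)
        if deficit > 0:
            exon_lens[-1] += deficit
        intron_lens = [
            int(x) for x in rng.integers(intron_lo, intron_hi + 1, len(exon_lens) - 1)
        ]

        spacer()
        gene_start = cursor
        exon_coords: list[tuple[int, int]] = []
        exon_seqs: list[str] = []
        for j, elen in enumerate(exon_lens):
            if j:
                emit(_random_seq(rng, intron_lens[j - 1]))
            eseq = _random_seq(rng, elen)
            estart = emit(eseq)
            exon_coords.append((estart, estart + elen))
            exon_seqs.append(eseq)
        gene_end = cursor

        model = TranscriptModel.from_coords(gid, f"{gid}.1", chrom, strand, exon_coords)
        transcripts.append(model)
        kind = "gene"
        if i == small_exon_idx:
            kind = "small_exon_gene"
        prov_rows.append(
            dict(
                element=gid,
                kind=kind,
                chrom=chrom,
                start=gene_start,
                end=gene_end,
                strand=strand,
                parent="",
                n_mutations=0,
            )
        )

        if i == paralog_idx:
            locus_seq = "".join(parts)[gene_start:gene_end]
            rel_coords = [(s - gene_start, e - gene_start) for s, e in exon_coords]
            paralog_locus = (locus_seq, rel_coords, strand, gid)
        if i not in (small_exon_idx, paralog_idx):
            mrna = "".join(exon_seqs)
            if strand == "-":
                mrna = reverse_complement(mrna)
            mrnas[gid] = mrna

    if paralog_locus is not None:
        locus_seq, rel_coords, strand, src_gid = paralog_locus
        spacer()
        copy_start = emit(locus_seq)
        gid2 = f"{src_gid}D"
        coords = [(copy_start + s, copy_start + e) for s, e in rel_coords]
        transcripts.append(
            TranscriptModel.from_coords(gid2, f"{gid2}.1", chrom, strand, coords)
        )
        prov_rows.append(
            dict(
                element=gid2,
                kind="identical_paralog",
                chrom=chrom,
                start=copy_start,
                end=copy_start + len(locus_seq),
                strand=strand,
                parent=src_gid,
                n_mutations=0,
            )
        )

    if config.include_retrocopies:
        # Processed pseudogenes derive from abundant, typically long mRNAs;
        # using the longest ordinary transcript as parent also keeps the
        # planted mutation count at percent-scale divergence.
        parent_gid = max(mrnas, key=lambda g: (len(mrnas[g]), g))
        mrna = mrnas[parent_gid]
        m = min(config.retrocopy_mutations, len(mrna))
        mutated = list(mrna)
        sites = rng.choice(len(mrna), size=m, replace=False)
        for s in sites:
            current = mutated[s]
            choices = [b for b in BASES if b != current]
            mutated[s] = choices[int(rng.integers(0, 3))]
        spacer()
        retro_start = emit("".join(mutated))
        prov_rows.append(
            dict(
                element=f"RETRO_{parent_gid}",
                kind="retrocopy",
                chrom=chrom,
                start=retro_start,
                end=retro_start + len(mrna),
                strand="+",
                parent=parent_gid,
                n_mutations=m,
            )
        )

    spacer()
    genome = {chrom: "".join(parts)}
    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "element",
            "kind",
            "chrom",
            "start",
            "end",
            "strand",
            "parent",
            "n_mutations",
        ],
    )
    return genome, Annotation(transcripts), provenance


def simulate_reads(
    genome: Mapping[str, str],
    annotation: Annotation,
    config: SimConfig,
    stream: str = "reads",
) -> tuple[list[SimRead], list[ReadTruth]]:
    """Draw reads uniformly per transcript base with substitution errors.

    Transcripts are chosen with probability proportional to spliced length
    and the start offset is uniform, i.e. coverage is uniform along each
    transcript.  Reads are emitted in the orientation of their transcript;
    the aligners are responsible for checking both orientations.  ``stream``
    salts the random substream so several samples can be drawn independently
    from one genome.
    """
    L = config.read_length
    rng = stage_rng(config.seed, f"reads:{stream}")
    models = sorted(annotation, key=lambda m: m.transcript_id)
    if not models:
        raise ValueError("annotation holds no transcripts")
    for m in models:
        if m.spliced_length < L:
            raise ValueError(
                f"transcript {m.transcript_id} spliced length {m.spliced_length} "
                f"is shorter than the read length {L}"
            )
    seqs = [transcript_sequence(m, genome) for m in models]
    weights = np.array([m.spliced_length for m in models], dtype=float)
    weights /= weights.sum()

    reads: list[SimRead] = []
    truths: list[ReadTruth] = []
    if config.n_reads == 0:
        return reads, truths
    picks = rng.choice(len(models), size=config.n_reads, p=weights)
    for i, mi in enumerate(picks):
        model = models[mi]
        splen = model.spliced_length
        t_start = int(rng.integers(0, splen - L + 1))
        window = seqs[mi][t_start : t_start + L]
        err_mask = rng.random(L) < config.error_rate
        n_errors = int(err_mask.sum())
        if n_errors:
            chars = list(window)
            for pos in np.flatnonzero(err_mask):
                current = chars[pos]
                choices = [b for b in BASES if b != current]
                chars[pos] = choices[int(rng.integers(0, 3))]
            window = "".join(chars)
        _, _, cigar = project_to_genome(model, t_start, L)
        span = sum(1 for op, _ in cigar if op == "M")
        rid = f"r{i:06d}"
        reads.append(SimRead(rid, window))
        truths.append(ReadTruth(rid, model.transcript_id, t_start, n_errors, span))
    return reads, truths


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    """Write reads with constant quality 'I' (Phred 40)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def truth_table(truths: Iterable[ReadTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                read_id=t.read_id,
                transcript_id=t.transcript_id,
                t_start=t.t_start,
                n_errors=t.n_errors,
                true_exon_span=t.true_exon_span,
            )
            for t in truths
        ],
        columns=["read_id", "transcript_id", "t_start", "n_errors", "true_exon_span"],
    )


def write_truth(truths: Iterable[ReadTruth], path: str | Path) -> None:
    truth_table(truths).to_csv(path, sep="\t", index=False)
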