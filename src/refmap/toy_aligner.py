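"""Minimal, fully enumerable spliced aligners for the two mapping strategies.

Two aligners share one candidate/selection machinery:

* :class:`GuidedAligner` -- transcriptome-first mapping.  Every placement of
  the read (both orientations) on every annotated transcript sequence with
  at most ``k_mismatch`` substitutions is found by pigeonhole k-mer seeding
  plus full Hamming verification, projected to genomic spliced coordinates,
  and de-duplicated.  If the transcriptome yields nothing, the read falls
  back to the genome-only aligner.

* :class:`GenomeOnlyAligner` -- de-novo seed-extend mapping.  Stage 1
  enumerates all contiguous genomic placements within the mismatch budget.
  Stage 2 discovers one-intron spliced placements: an exact prefix anchor
  and an exact suffix anchor (each ``min_anchor`` bases) on the same
  chromosome and orientation, separated so the implied intron falls in
  ``intron_range``; every split of the read into two blocks of at least
  ``min_anchor`` bases whose interior mismatches stay within budget becomes
  a candidate.  At most one intron per read is representable -- reads
  spanning three or more exons are structurally unrecoverable de novo.

Scoring is (mismatches, then number of introns); the remaining tie-break is
total and documented (intron length, leftmost coordinate, chromosome,
block list), so unique-mode reporting is deterministic.  In unique mode a
read with more than one best-scoring distinct placement is reported
unmapped with the tie count; in multiple mode all tied placements are
reported up to ``max_locations`` with an NH tag.

Substitutions only; no indels, no soft clipping, no splice-motif scoring.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

from .annotation_io import (
    AlignmentRecord,
    Annotation,
    project_to_genome,
    transcript_sequence,
)

__all__ = [
    "AlignerConfig",
    "CandidateHit",
    "GuidedAligner",
    "GenomeOnlyAligner",
    "align_guided",
    "align_genome_only",
    "select_placements",
]

MODES = ("unique", "multiple")


@dataclass
class AlignerConfig:
    """Tunable parameters shared by both aligners.

    ``k_mismatch`` bounds substitutions per alignment; ``seed_length`` is the
    exact k-mer used for pigeonhole seeding (completeness requires
    ``(k_mismatch + 1) * seed_length <= read length``); ``min_anchor`` is the
    smallest exonic block the de-novo splice search will place;
    ``intron_range`` bounds the N gap; ``max_locations`` caps multiple-mode
    reporting.
    """

    k_mismatch: int = 2
    seed_length: int = 20
    min_anchor: int = 8
    intron_range: tuple[int, int] = (40, 50000)
    mode: str = "unique"
    max_locations: int = 2000

    def __post_init__(self) -> None:
        if self.min_anchor < 1:
            raise ValueError("min_anchor must be >= 1")
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        if self.k_mismatch < 0:
            raise ValueError("k_mismatch must be >= 0")
        if self.max_locations < 1:
            raise ValueError("max_locations must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.intron_range[0] < 1 or self.intron_range[0] > self.intron_range[1]:
            raise ValueError(f"bad intron_range {self.intron_range}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AlignerConfig":
        """Parse a ``key = value`` config file mirroring the field names."""
        kwargs: dict = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key in ("k_mismatch", "seed_length", "min_anchor", "max_locations"):
                    kwargs[key] = int(value)
                elif key == "intron_range":
                    lo, hi = value.replace(",", " ").split()
                    kwargs[key] = (int(lo), int(hi))
                elif key == "mode":
                    kwargs[key] = value
                else:
                    raise ValueError(f"unknown aligner config key {key!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class CandidateHit:
    """One candidate genomic placement of a read (internal plumbing)."""

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    nm: int

    @property
    def pos(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.blocks) - 1

    @property
    def intron_span(self) -> int:
        return (self.end - self.pos) - sum(e - s for s, e in self.blocks)


def _hamming_le(a: str, b: str, k: int) -> int | None:
    """Hamming distance of equal-length strings, or None once it exceeds k."""
    if a == b:
        return 0
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > k:
                return None
    return mismatches


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> tuple[tuple[str, int], ...]:
    cigar: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i:
            cigar.append(("N", s - blocks[i - 1][1]))
        cigar.append(("M", e - s))
    return tuple(cigar)


class _KmerIndex:
    """Exact k-mer -> (sequence name, offset) index over a set of sequences."""

    def __init__(self, seqs: Mapping[str, str], k: int) -> None:
        self.k = k
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name in seqs:
            s = seqs[name]
            for i in range(len(s) - k + 1):
                index[s[i : i + k]].append((name, i))
        self._index = dict(index)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, ())


def _pigeonhole_hits(
    q: str,
    targets: Mapping[str, str],
    index: _KmerIndex,
    k_mismatch: int,
) -> dict[tuple[str, int], int]:
    """All placements of ``q`` on the targets with <= k_mismatch substitutions.

    Pigeonhole: the read is covered by ``k_mismatch + 1`` disjoint seed
    windows, at least one of which must be error-free in any valid placement,
    so seeding each window and Hamming-verifying every candidate offset is
    complete.
    """
    L = len(q)
    k = index.k
    nseg = k_mismatch + 1
    if nseg * k > L:
        raise ValueError(
            f"(k_mismatch + 1) * seed_length = {nseg * k} exceeds read length {L}; "
            "reduce seed_length or k_mismatch"
        )
    offsets = [(i * L) // nseg for i in range(nseg)]
    hits: dict[tuple[str, int], int] = {}
    visited: set[tuple[str, int]] = set()
    for o in offsets:
        for name, p in index.lookup(q[o : o + k]):
            start = p - o
            key = (name, start)
            if key in visited:
                continue
            visited.add(key)
            target = targets[name]
            if start < 0 or start + L > len(target):
                continue
            nm = _hamming_le(q, target[start : start + L], k_mismatch)
            if nm is not None:
                hits[key] = nm
    return hits


def select_placements(
    read_id: str, candidates: Sequence[CandidateHit], cfg: AlignerConfig
) -> list[AlignmentRecord]:
    """Apply scoring, tie-breaking and the reporting mode to candidates.

    The best score is the lexicographic minimum of (mismatches, introns);
    distinct placements achieving it are counted for the unique/multiple
    decision, and the remaining tie-break (total intron length, leftmost
    position, chromosome, strand, block list) fixes the reported order.
    """
    if not candidates:
        return [AlignmentRecord(read_id=read_id, mapped=False, n_locations=0)]
    best_score = min((c.nm, c.n_introns) for c in candidates)
    unique: dict[tuple, CandidateHit] = {}
    for c in candidates:
        if (c.nm, c.n_introns) == best_score:
            unique.setdefault((c.chrom, c.strand, c.blocks), c)
    placements = sorted(
        unique.values(),
        key=lambda c: (c.intron_span, c.pos, c.chrom, c.strand, c.blocks),
    )
    n = len(placements)

    def record(c: CandidateHit, secondary: bool) -> AlignmentRecord:
        return AlignmentRecord(
            read_id=read_id,
            mapped=True,
            chrom=c.chrom,
            pos=c.pos,
            strand=c.strand,
            cigar=_blocks_to_cigar(c.blocks),
            nm=c.nm,
            n_locations=n,
            secondary=secondary,
        )

    if cfg.mode == "unique":
        if n == 1:
            return [record(placements[0], False)]
        return [AlignmentRecord(read_id=read_id, mapped=False, n_locations=n)]
    reported = placements[: cfg.max_locations]
    return [record(c, i > 0) for i, c in enumerate(reported)]


class GenomeOnlyAligner:
    """De-novo contiguous + one-intron spliced alignment against the genome."""

    def __init__(self, genome: Mapping[str, str], cfg: AlignerConfig | None = None):
        self.cfg = cfg if cfg is not None else AlignerConfig()
        self.genome = {name: genome[name].upper() for name in genome}
        self._seed_index = _KmerIndex(self.genome, self.cfg.seed_length)
        if self.cfg.min_anchor == self.cfg.seed_length:
            self._anchor_index = self._seed_index
        else:
            self._anchor_index = _KmerIndex(self.genome, self.cfg.min_anchor)

    # -- stage 1: contiguous ------------------------------------------------
    def _contiguous(self, q: str, strand: str) -> list[CandidateHit]:
        hits = _pigeonhole_hits(q, self.genome, self._seed_index, self.cfg.k_mismatch)
        return [
            CandidateHit(chrom, strand, ((pos, pos + len(q)),), nm)
            for (chrom, pos), nm in hits.items()
        ]

    # -- stage 2: one-intron spliced ---------------------------------------
    def _spliced(self, q: str, strand: str) -> list[CandidateHit]:
        cfg = self.cfg
        a = cfg.min_anchor
        k = cfg.k_mismatch
        L = len(q)
        if L < 2 * a:
            return []
        imin, imax = cfg.intron_range
        prefix = q[:a]
        suffix = q[L - a :]
        lefts = self._anchor_index.lookup(prefix)
        rights = self._anchor_index.lookup(suffix)
        if not lefts or not rights:
            return []
        rights_by_chrom: dict[str, list[int]] = defaultdict(list)
        for chrom, p in rights:
            rights_by_chrom[chrom].append(p)  # ascending by construction
        out: list[CandidateHit] = []
        for chrom, g in lefts:
            positions = rights_by_chrom.get(chrom)
            if not positions:
                continue
            gseq = self.genome[chrom]
            if g + (L - a) > len(gseq):
                continue
            # intron length = h + a - L - g must fall inside intron_range
            lo = bisect_left(positions, g + L - a + imin)
            hi = bisect_right(positions, g + L - a + imax)
            if lo == hi:
                continue
            left_mis = [q[j] != gseq[g + j] for j in range(L - a)]
            cum_left = [0] * (L - a + 1)
            for j in range(L - a):
                cum_left[j + 1] = cum_left[j] + left_mis[j]
            for h in positions[lo:hi]:
                shift = h + a - L
                if shift + a < 0 or h + a > len(gseq):
                    continue
                # mismatch indicator of q[j] against the right-side frame
                suf_right = [0] * (L + 1)
                for j in range(L - 1, a - 1, -1):
                    miss = q[j] != gseq[shift + j]
                    suf_right[j] = suf_right[j + 1] + (1 if miss else 0)
                intron = h + a - L - g
                for b1 in range(a, L - a + 1):
                    nm = cum_left[b1] + suf_right[b1]
                    if nm > k:
                        continue
                    blocks = ((g, g + b1), (shift + b1, h + a))
                    out.append(CandidateHit(chrom, strand, blocks, nm))
        return out

    def candidates(self, seq: str) -> list[CandidateHit]:
        oriented = (("+", seq), ("-", reverse_complement(seq)))
        cands: list[CandidateHit] = []
        for strand, q in oriented:
            cands.extend(self._contiguous(q, strand))
        # Splice discovery is a rescue for contiguously unplaceable reads
        # (the two-step design of de-novo spliced aligners).  Attempting it
        # for every read would let a sequencing error in a read's first or
        # last bases be "explained away" as a spurious intron whenever the
        # short tail finds an exact match within intron range, silently
        # converting exonic reads into junction reads.
        if not cands:
            for strand, q in oriented:
                cands.extend(self._spliced(q, strand))
        return cands

    def align(self, read_id: str, seq: str) -> list[AlignmentRecord]:
        return select_placements(read_id, self.candidates(seq.upper()), self.cfg)


class GuidedAligner:
    """Transcriptome-first alignment with genomic projection and fallback."""

    def __init__(
        self,
        genome: Mapping[str, str],
        annotation: Annotation,
        cfg: AlignerConfig | None = None,
    ) -> None:
        self.cfg = cfg if cfg is not None else AlignerConfig()
        self.annotation = annotation
        self._tx_seqs = {
            tid: transcript_sequence(model, genome)
            for tid, model in annotation.transcripts.items()
        }
        self._tx_index = _KmerIndex(self._tx_seqs, self.cfg.seed_length)
        self._fallback = GenomeOnlyAligner(genome, self.cfg)

    def candidates(self, seq: str) -> list[CandidateHit]:
        cands: dict[tuple, CandidateHit] = {}
        for sense, q in ((True, seq), (False, reverse_complement(seq))):
            hits = _pigeonhole_hits(q, self._tx_seqs, self._tx_index, self.cfg.k_mismatch)
            for (tid, t0), nm in hits.items():
                model = self.annotation.transcripts[tid]
                pos, tx_strand, cigar = project_to_genome(model, t0, len(q))
                strand = tx_strand if sense else ("-" if tx_strand == "+" else "+")
                blocks: list[tuple[int, int]] = []
                cur = pos
                for op, ln in cigar:
                    if op == "M":
                        blocks.append((cur, cur + ln))
                    cur += ln
                key = (model.chrom, strand, tuple(blocks))
                hit = CandidateHit(model.chrom, strand, tuple(blocks), nm)
                prev = cands.get(key)
                if prev is None or nm < prev.nm:
                    cands[key] = hit
        return list(cands.values())

    def align(self, read_id: str, seq: str) -> list[AlignmentRecord]:
        seq = seq.upper()
        cands = self.candidates(seq)
        if not cands:
            return self._fallback.align(read_id, seq)
        return select_placements(read_id, cands, self.cfg)


def _as_read(read) -> tuple[str, str]:
    if hasattr(read, "read_id") and hasattr(read, "sequence"):
        return read.read_id, read.sequence
    read_id, seq = read
    return read_id, seq


def align_guided(
    read,
    annotation: Annotation,
    genome: Mapping[str, str],
    cfg: AlignerConfig | None = None,
) -> list[AlignmentRecord]:
    """One-shot guided alignment of a single read (builds indexes each call).

    ``read`` is a ``(read_id, sequence)`` pair or any object with
    ``read_id``/``sequence`` attributes.  For many reads, instantiate
    :class:`GuidedAligner` once and call ``align`` per read.
    """
    read_id, seq = _as_read(read)
    return GuidedAligner(genome, annotation, cfg).align(read_id, seq)


def align_genome_only(
    read,
    genome: Mapping[str, str],
    cfg: AlignerConfig | None = None,
) -> list[AlignmentRecord]:
    """One-shot de-novo alignment of a single read (builds indexes each call)."""
    read_id, seq = _as_read(read)
    return GenomeOnlyAligner(genome, cfg).align(read_id, seq)
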