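"""Shared fixtures: synthetic study runs and hand-built mechanism genomes."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from refmap.annotation_io import Annotation, TranscriptModel, transcript_sequence
from refmap.compare_engine import pair_records, summarize
from refmap.synthetic_data import SimConfig, SimRead, make_genome, simulate_reads
from refmap.toy_aligner import AlignerConfig, GuidedAligner, select_placements


def align_unique_runs(genome, annotation, reads, acfg=None):
    """Align reads with both strategies in unique mode (guided run A, de-novo run B)."""
    acfg = acfg or AlignerConfig()
    guided = GuidedAligner(genome, annotation, acfg)
    genome_only = guided._fallback
    records_a, records_b = [], []
    for read in reads:
        guided_cands = guided.candidates(read.sequence)
        genome_cands = genome_only.candidates(read.sequence)
        effective = guided_cands if guided_cands else genome_cands
        records_a.extend(select_placements(read.read_id, effective, acfg))
        records_b.extend(select_placements(read.read_id, genome_cands, acfg))
    return records_a, records_b


def _study(sim_cfg: SimConfig) -> SimpleNamespace:
    genome, annotation, provenance = make_genome(sim_cfg)
    reads, truths = simulate_reads(genome, annotation, sim_cfg, stream="sample1")
    acfg = AlignerConfig()
    records_a, records_b = align_unique_runs(genome, annotation, reads, acfg)
    comparisons = pair_records(records_a, records_b)
    return SimpleNamespace(
        cfg=sim_cfg,
        acfg=acfg,
        genome=genome,
        annotation=annotation,
        provenance=provenance,
        reads=reads,
        truths={t.read_id: t for t in truths},
        records_a=records_a,
        records_b=records_b,
        by_a={r.read_id: r for r in records_a},
        by_b={r.read_id: r for r in records_b},
        comparisons=comparisons,
        summary=summarize(comparisons),
    )


@pytest.fixture(scope="session")
def default_study():
    """The full-scale seed-fixed synthetic run under default study conditions."""
    return _study(SimConfig(seed=1, n_reads=20000))


@pytest.fixture(scope="session")
def errorfree_study():
    """A noise-free run: every read is an exact transcript substring."""
    return _study(SimConfig(seed=2, n_reads=6000, error_rate=0.0))


def _random_genome(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _plant(genome: str, pos: int, segment: str) -> str:
    return genome[:pos] + segment + genome[pos + len(segment) :]


@pytest.fixture(scope="session")
def retrocopy_fixture():
    """A two-exon parent gene plus an unannotated, lightly mutated retrocopy.

    The retrocopy is the parent's mRNA with two substitutions placed far
    from the junction-derived region, so error-free junction reads of the
    parent see a perfect (0-mismatch) contiguous copy of their sequence at
    the retrocopy locus.
    """
    g = _random_genome(101, 9000)
    model = TranscriptModel.from_coords(
        "PARENT", "PARENT.1", "chr1", "+", [(1000, 1600), (2200, 2800)]
    )
    annotation = Annotation([model])
    genome = {"chr1": g}
    mrna = transcript_sequence(model, genome)  # length 1200, junction at 600
    mutated = list(mrna)
    for site in (100, 1100):  # far from the junction neighbourhood
        mutated[site] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[site]]
    retro_start = 6000
    genome = {"chr1": _plant(g, retro_start, "".join(mutated))}
    return SimpleNamespace(
        genome=genome,
        annotation=annotation,
        model=model,
        mrna=transcript_sequence(model, genome),
        retro_interval=(retro_start, retro_start + len(mrna)),
    )


@pytest.fixture(scope="session")
def paralog_fixture():
    """One gene present as two byte-identical annotated loci."""
    g = _random_genome(202, 9000)
    locus = g[1000:2200]
    genome = {"chr1": _plant(g, 6000, locus)}
    coords = [(1000, 1300), (1900, 2200)]
    model_a = TranscriptModel.from_coords("DUPA", "DUPA.1", "chr1", "+", coords)
    model_b = TranscriptModel.from_coords(
        "DUPB", "DUPB.1", "chr1", "+", [(s + 5000, e + 5000) for s, e in coords]
    )
    annotation = Annotation([model_a, model_b])
    return SimpleNamespace(
        genome=genome,
        annotation=annotation,
        model_a=model_a,
        model_b=model_b,
        mrna=transcript_sequence(model_a, genome),
    )


@pytest.fixture(scope="session")
def small_exon_fixture():
    """A gene with a 6 bp internal exon flanked by normal exons."""
    genome = {"chr1": _random_genome(303, 6000)}
    model = TranscriptModel.from_coords(
        "TINY",
        "TINY.1",
        "chr1",
        "+",
        [(1000, 1150), (1300, 1306), (1500, 1650)],
    )
    annotation = Annotation([model])
    return SimpleNamespace(
        genome=genome,
        annotation=annotation,
        model=model,
        mrna=transcript_sequence(model, genome),
    )


def reads_from_transcript(mrna: str, t_starts, length: int = 75, prefix: str = "q"):
    return [
        SimRead(f"{prefix}{i:03d}", mrna[t : t + length])
        for i, t in enumerate(t_starts)
    ]
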