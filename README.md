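# refmap

**What does a reference transcriptome actually buy you when mapping short
RNA-seq reads?** `refmap` is a desk-scale, fully self-contained pipeline for
answering that question. It simulates a genome containing the structural
features that make spliced alignment hard, maps 75 bp reads with and without
annotation guidance using two small, fully specified aligners, and measures —
read by read and gene by gene — what is lost when the annotation is withheld.

It is aimed at people teaching or studying RNA-seq alignment methodology:
every phenomenon is reproducible from a seed, every read carries ground
truth, and every aligner decision is enumerable and oracle-checkable.

## The comparison

Reads are aligned in three runs:

1. **guided / unique** — reads are placed on annotated transcript sequences
   first (all placements within a mismatch budget *k*, found by pigeonhole
   k-mer seeding + Hamming verification), projected to spliced genomic
   coordinates (`M`/`N` CIGAR), with a genomic fallback; only reads with a
   single best placement are reported.
2. **de-novo / unique** — genome only: contiguous placements, and for
   contiguously unplaceable reads a one-intron seed–extend search (exact
   anchors of ≥ *a* bases on both sides of a candidate intron).
3. **guided / multiple** — as (1), but all tied best placements are
   reported, up to a cap, with an `NH` tag.

Every read mapped in run 1 is then assigned a fate in run 2:

* **Identical** — same chromosome, strand and exact block list;
* **Alternative** — mapped, but to a different region or splice;
* **Unmapped** — lost without the annotation.

Junction reads (alignments spanning ≥ 2 exons, i.e. with `N` CIGAR
operations) are characterized by their exon span and by
**MOE = min(O<sub>L</sub>, O<sub>R</sub>)**, the minimum overlap of the read
with its flanking exons; for a 75 bp read MOE ranges from 1 to 37. Gene-level
impact uses intersection-strict counting, the ≥ 20 % count-reduction gene
list, and between-sample log₂ fold-change concordance with discordance flags
at |Δlog₂FC| > 2 and > 3.3.

The simulated genome plants the three classic confounders, with per-read
ground truth:

* a **retrotransposed pseudogene** — an unannotated, lightly mutated,
  intronless copy of one gene's mRNA, which captures that gene's junction
  reads under de-novo alignment;
* an **identical paralog** — a byte-identical second copy of a gene's locus,
  both annotated, whose expression collapses to zero in unique-mapping mode;
* a **small-exon gene** — a run of short internal exons including a 6 bp
  exon, whose junction reads cannot be anchored without prior knowledge.

## Worked example

```sh
refmap all --seed 7 --n-reads 4000 --n-genes 12 --out demo/
```

prints (excerpt):

```
| run | total reads | uniquely mapped % | non-uniquely mapped % | unmapped % |
| refgene_unique | 4000 | 90.58 | 0.00 | 9.43 |
| none_unique | 4000 | 73.72 | 0.00 | 26.27 |
| refgene_multiple | 4000 | 90.58 | 9.03 | 0.40 |

| category | reads | % | junction reads | junction % | junction fraction % |
| Identical | 2605 | 71.90 | 479 | 36.10 | 18.39 |
| Alternative | 339 | 9.36 | 338 | 25.47 | 99.71 |
| Unmapped | 679 | 18.74 | 510 | 38.43 | 75.11 |
| all | 3623 | 100.00 | 1327 | 100.00 | 36.63 |
```

Reading this: withholding the annotation costs ~17 percentage points of
uniquely mapped reads (90.6 % → 73.7 %). Of the reads the guided run placed,
18.7 % are lost outright and 9.4 % move — and those two categories are
almost entirely junction reads (75 % and 99.7 % junction fraction, against
36.6 % overall). The exon-span table in the full report shows identical
recovery falling from ~38 % for two-exon junction reads to exactly zero for
reads spanning three or more exons (the one-intron de-novo search cannot
represent them), and the MOE histograms show Alternative reads piling up at
MOE ≤ 3 while identically recovered junction reads all have MOE ≥ 8 (the
anchor length). The gene-count table ends:

```
5 genes lost at least 20% of their reads without the annotation.
| G0003 | 765 | 332 | 56.6 |   <- the retrocopy parent
...
11 genes; |delta log2FC| > 2 for 0 (blue), > 3.3 for 0 (red); max delta 0.110.
```

The same library surface is available programmatically
(`refmap.run_pipeline`, or the individual modules `synthetic_data`,
`toy_aligner`, `compare_engine`, `quant_impact`), and the CLI exposes each
stage separately (`simulate`, `align`, `compare`, `impact`, `concordance`).
Externally produced name-matched SAM pairs plus a GTF can be fed straight
into `refmap compare` / `refmap impact`.

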