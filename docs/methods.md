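# Methods

This note records the models, parameter choices and numerical conventions
behind `refmap`, and what its synthetic results do and do not say about real
data.

## Coordinates and formats

All coordinates are 0-based half-open internally; 1-based conventions exist
only at the GTF (1-based inclusive) and SAM (1-based POS) file boundaries.
The GTF reader accepts the UCSC Table-Browser exon dialect only (exon
feature lines with `gene_id`/`transcript_id` attributes) and rejects
structurally broken lines with their line number; other feature types are
ignored. SAM is plain text with mandatory `@SQ` headers; `NM` carries the
substitution count and `NH` the number of equally-best placements (also on
unmapped records that were dropped for ambiguity, where it records the tie
count). CIGAR vocabulary is `M I D N S`; `=`/`X` are normalized to `M` on
input. Unmapped records carry no placement fields.

## The synthetic genome and reads

The generator is the package's study design: it does not imitate any
particular genome, it plants the *mechanisms* whose consequences are being
measured, with full ground truth.

One chromosome carries `n_genes` genes (default 30), each with 2–8 exons of
20–300 bp (exon lengths around and below the read length, so junction reads
are common) and introns of 60–1500 bp, on random strands, separated by
300–800 bp intergenic spacers. Three special loci are planted:

* **Small-exon gene** (gene index 0): exon lengths ~150 / 30 / 6 / 30 /
  ~150. The run of short internal exons mirrors the cardiac-troponin-like
  gene structure in which single reads span three or more exons and a 6 bp
  exon must be crossed; it is what populates the 3- and 4+-exon-span rows of
  the summaries.
* **Identical paralog** (gene index 1): the gene's whole locus is duplicated
  byte-for-byte downstream and both copies are annotated, modelling recent
  undiverged duplicates whose reads are inherently ambiguous.
* **Retrocopy**: the mature mRNA of the *longest* ordinary transcript,
  carrying exactly `retrocopy_mutations` substitutions (default 20),
  inserted intergenically and deliberately **absent from the annotation**.
  Parents of processed pseudogenes are typically long, highly expressed
  mRNAs; choosing the longest transcript also makes the default mutation
  count a percent-scale divergence (~1–2 %), so a 75 bp read window over the
  retrocopy usually differs from the parent mRNA at one or two bases — the
  regime in which pseudogenes capture reads with visible mismatches rather
  than being exact duplicates.

Reads (default 20 000 per sample, 75 bp) are drawn per transcript with
probability proportional to spliced length and uniform start within the
transcript, in the orientation of the transcript, with independent per-base
substitutions at `error_rate` (default 0.005, a typical short-read
substitution scale). Qualities are constant (`I`); there are no indels, no
fragment-length model, no expression heterogeneity between genes or between
samples. Each read's truth records its transcript, offset, error count and
true exon span.

Randomness: one master seed; every stage draws from an independent
substream salted by a stage name (CRC32 of the name mixed into the seed
sequence), so enlarging one stage never perturbs another, and two samples
drawn from one genome are independent.

## The aligners

Both aligners share one scoring and selection machinery and are restricted
to substitutions (no indels, no soft clipping, no splice-motif model) so
that every candidate class is exhaustively enumerable and testable against
brute-force oracles.

**Candidate generation.** Guided: all placements of the read (both
orientations) on every annotated transcript sequence with ≤ `k_mismatch`
(default 2) substitutions, found by pigeonhole seeding — the read is covered
by `k+1` disjoint exact seeds of `seed_length` (default 20) bases, so any
valid placement leaves at least one seed error-free — then verified by full
Hamming comparison and projected through the transcript model to spliced
genomic coordinates. Duplicate genomic placements from overlapping
transcripts are collapsed. If the transcriptome yields nothing the read
falls back to the de-novo aligner. De-novo: stage 1 enumerates contiguous
genomic placements the same way; stage 2, **only for reads with no
contiguous candidate at all**, searches one-intron placements: an exact
prefix anchor and exact suffix anchor of `min_anchor` (default 8) bases on
the same chromosome and orientation with an implied intron in
`intron_range` (default 40–50 000), and every two-block split with blocks
≥ `min_anchor` whose interior mismatches stay within budget.

The two-step gating of stage 2 is a deliberate design choice. If splice
discovery competed for every read, a substitution in a read's terminal bases
could always be "explained away" as a spurious intron — an exact 8-mer match
for the tail is expected within a 50 kb window — silently converting ~1 % of
exonic reads into junction reads and, conversely, letting a perfect spliced
placement always out-score a pseudogene placement with one mismatch, which
would erase pseudogene capture entirely. Treating splice discovery as a
rescue for contiguously unplaceable reads is the behaviour of two-step
spliced aligners and produces both phenomena correctly: captures carry
*more* mismatches than the guided placement they replace, and exonic reads
stay exonic.

**Scoring and ties.** Best score is (fewest mismatches, then fewest
introns). The remaining tie-break is total and documented: total intron
length, leftmost coordinate, chromosome, strand, block list — so unique-mode
output is deterministic. A *placement* is a (chromosome, strand, block
list) triple; in unique mode a read whose best score is achieved by more
than one distinct placement is reported unmapped with the tie count in
`NH`. This is strict: two placements differing only in the splice split
(the same region, an ambiguous intron boundary) also count as a tie and the
read is dropped rather than arbitrarily resolved. In multiple mode all tied
placements are reported up to `max_locations` (default 2000).

Consequences worth knowing: with one intron per read, de-novo recovery of
reads spanning ≥ 3 exons is structurally zero — the decrease of identical
recovery with exon span is a designed property, not a tuning outcome; and a
junction read whose overlap with one exon is below the anchor length can
only be recovered contiguously (running `MOE` bases into the intron, if
within the mismatch budget, typically for MOE ≤ 3) or lost — which is what
shapes the MOE histograms of the Alternative and Unmapped categories.

## Comparison and summaries

Classification is placement-level: Identical requires equal chromosome,
strand and ordered block list; mismatch counts and tags are ignored (the
question is *where*, not *how well*). Strand disagreement alone counts as
Alternative by default (`strand_matters` flag exposed). Blocks are compared
block-wise, not as CIGAR strings, so `10M10M` equals `20M`. The comparison
is defined over reads mapped in the guided run: reads unmapped there are
counted but not categorized, and reads mapped only in the de-novo run are
logged and ignored. Secondary (multiple-mode) records are excluded;
comparison inputs are unique-mode runs.

Junction status, exon span and MOE always come from the guided profile.
MOE is generalized to min(first block, last block) for ≥ 3-block profiles,
but histograms are computed on two-block profiles only, where 1 ≤ MOE ≤
⌊L/2⌋ holds exactly.

## Quantification

Intersection-strict counting: a read counts for gene G iff every block lies
inside exons of at least one transcript of G and G is the only such gene; a
`union` mode (any exonic overlap, still unambiguous) is provided. The
reduction list keeps genes with `count_A > 0` and
`100·(count_A − count_B)/count_A ≥ 20 %` by default. Fold changes use
library-size normalization (both samples scaled to the mean of their
totals) and a pseudocount of 0.5: `log2((n₁ + 0.5)/(n₂ + 0.5))`; the
pseudocount and thresholds (strictly greater than 2 → "blue", 3.3 → "red")
are parameters. The published analyses this mirrors do not specify their
fold-change formula; this simple normalized form is a documented choice,
antisymmetric under sample swap by construction.

Because the generator gives every gene the same per-base sampling rate in
both samples, true fold changes are ~0 everywhere and annotation-dependent
count losses affect both samples alike, so the default study produces *no*
discordance flags — the flag machinery is exercised by tests on constructed
counts. Producing figure-style discordance clouds would require an
expression contrast between samples, which the generator deliberately does
not model.

## Problem sizes and determinism

Default study conditions: 20 000 reads × 75 bp per sample, 30 genes
(~150 kb genome), two samples for concordance. The whole pipeline is a few
seconds on one CPU; the acceptance script is well under a minute. Reruns
with identical configuration are byte-identical for all TSV outputs (no
hidden global randomness; all iteration orders are fixed).

## Known limitations

* Substitution-only alignment; indels, soft clipping, paired ends and
  quality-aware scoring are out of scope.
* No splice-motif (GT–AG) model; intron plausibility is a length range.
* One intron per read in de-novo mode (by design, see above).
* The simulated genome is i.i.d. random sequence: no repeat families, GC
  structure or homopolymers, so mapping ambiguity outside the planted
  confounders is rarer than in real genomes. Passing tests demonstrate the
  mechanisms and the correctness of the machinery, not quantitative rates
  for any real organism.
* Single-transcript genes except where planted otherwise; alternative
  splicing within a gene is not simulated (the machinery supports it — the
  annotation may hold any number of transcripts per gene).
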