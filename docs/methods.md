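# Methods

## The workflow

`targetfirst` implements a three-step, target-first analysis of paired-end
whole-genome sequencing data, built around a compact **Target Reference
Genome**:

1. **Target selection.** All read pairs are aligned to the target
   reference — the padded, merged exonic regions of a chosen gene set,
   extracted as individual contigs.  A pair is *selected* when at least
   one mate maps anywhere on it, regardless of MAPQ.
2. **Whole-genome correction.** Selected pairs are realigned to the whole
   genome.  Reads that were only *forcibly* captured (their best locus —
   typically a segmental paralog of a target gene — lies outside the
   targets) relocate; pairs with no mate overlapping a target region are
   removed from the target set, keeping their genome alignments.  Variants
   in the target regions are then called from the retained alignments and
   reported immediately.
3. **Deferred remainder.** Unselected pairs are aligned to the whole
   genome, merged with the removed and retained alignments into one
   coordinate-sorted set, and variants are called genome-wide.  Step 3
   never touches the early report.

Selection is pair-level by default (`--read-level` switches to per-mate)
because the pad is sized for whole fragments: discarding the unmapped mate
of a boundary pair would throw away exactly the reads the pad exists to
keep.  Step-1 selection deliberately ignores MAPQ — a multi-mapping, forced
alignment is still selected, because step 2 (realignment), not a MAPQ
threshold, is the correction mechanism.  Removed pairs are *not* aligned a
third time in step 3; step 2 already produced their whole-genome
alignments.

## Target reference construction

Exons are read from a refFlat-dialect annotation restricted to a
user-supplied gene list.  Each exon is extended symmetrically by a **pad**
(default 550 bp, sized so that a whole sequencing fragment of roughly
400 bp overlapping an exon fits inside the extended region), clamped to the
sequence ends.  Overlapping and book-ended padded intervals are merged into
maximal disjoint regions before extraction, so each genomic base occurs at
most once in the target reference; duplicated bases would make step-1
alignments ambiguous and defeat selection.  Each merged region becomes one
forward-strand contig named `seq:start-end` (0-based, half-open) rather
than being concatenated into a single contig, which would invite chimeric
alignments across region junctions.  A `--no-merge` flag reproduces the
literal pad-and-concatenate reading.  A 5-column TSV **TargetMap**
accompanies the FASTA and gives exact bidirectional liftover; coordinates
are 0-based half-open everywhere internally and 1-based only in SAM/VCF
output.

### Capture model

`estimate_uncaptured_pair_fraction` estimates, for a pad *P*, exon length
*L* and fragment-length distribution, the fraction of exon-overlapping
fragments not fully contained in the padded region.  The model: a fragment
of length *F* starts uniformly over the *L + F* (continuous) placements
that overlap the exon, and is captured iff it lies inside `[-P, L+P)`.
The per-length uncaptured fraction is `min(1, max(0, 2(F-P)) / (L+F))`
(the clamp only matters in the degenerate case `F > L + 2P`), averaged
over the fragment distribution discretized to integer lengths.  The
estimate is oracle-tested against Monte-Carlo placement; with the default
normal(397, 80) model truncated to [250, 700] and `P = 550`, `L = 280` it
is ≈ 0.2 %.  Empirical fragment-length distributions can be supplied; no
claim is made for any particular instrument's distribution.

## Built-in aligner

The pipeline is aligner-agnostic (any `AlignerContract`; an
`exec:<template>` adapter wraps external SAM-emitting aligners).  The
built-in aligner exists so everything runs hermetically and
deterministically; it is deliberately simple and does not aim at parity
with production aligners:

* exact k-mer seeding (default k = 21, odd, 11–31), non-overlapping read
  k-mers plus one tail seed, both orientations, against a forward-strand
  index; seeds with more than 64 hits are skipped;
* banded end-to-end extension at each candidate locus by edit distance
  (edlib), edit budget 5 % of read length (so indels up to ~5 bp in a
  100 bp read), band 2 × budget;
* best locus by edit distance, ties broken by lowest (sequence name,
  position); MAPQ 60 when unique, 0 on ties, otherwise
  `min(60, 6 × (second − best))` — any monotone scheme suffices since the
  workflow filters on position, not MAPQ;
* pair rescoring: among each mate's candidates, a same-sequence,
  opposite-orientation, forward-reverse combination with implied fragment
  length inside the fragment model's truncation bounds is preferred when
  its total edit distance matches the unconstrained optimum; a pairing
  that resolves a mate's tie lends that mate the pair's MAPQ.

Base qualities are carried through but not used for alignment scoring
(recalibration is out of scope).  Known limitations: no clipping or
split/chimeric alignments, no secondary records, indels beyond the edit
budget are unalignable — an 8 bp deletion under 100 bp reads will surface
as missing coverage or fringe calls, identically in both workflows.

## Genotyper

A pileup caller with conventional, configurable thresholds (the upstream
production caller it stands in for is out of scope, and no equivalence
with it is claimed).  Bases below quality 13 and reads below MAPQ 10 are
excluded.  At each column the most frequent non-reference allele is the
candidate ALT; with alt fraction *f*, genotype is hom-ref (no record) for
*f* < 0.2, het for 0.2 ≤ *f* ≤ 0.8, hom-alt above.  QUAL is the
phred-scaled likelihood ratio of the called genotype against the next best
under binomial sampling of alt reads with P(alt) = ε, ½, 1−ε for 0/0, 0/1,
1/1, where ε is the column's mean base-error (clamped to [1e-6, 0.25]);
the binomial coefficient cancels.  Indels are left-anchored at the
preceding base; the anchor replaces the read's plain-base observation.
Only the top ALT is emitted (the evaluation truth panels are biallelic).
VCF 4.2 output carries INFO DP (ref+alt supporting depth), QD (QUAL/DP)
and SB (ref-fwd, ref-rev, alt-fwd, alt-rev), FORMAT GT:DP.

One consequence of the called-vs-next-best QUAL: for a clean hom-alt
column the next-best genotype is het, giving ≈ 10·log10(2) ≈ 3 per
supporting read, so hom-alt calls sit near QD 3 regardless of depth.  The
QD < 5 gate in the QC cascade therefore separates confident het calls and
conservatively flags hom-alt exclusives; this is deliberate — the cascade
only ever classifies calls that already disagree between workflows or
with truth.

## Evaluation

* **Genotype concordance** versus an array-style truth panel
  (chrom, pos, ref, unordered genotype).  A covered truth site with no
  VCF record is an implied hom-ref call — array concordance needs
  genotypes at non-variant sites, and this is the standard reading that
  keeps the accounting identity `concordant + discordant + no-call =
  sites`.  A site with zero usable aligned depth is a no-call and leaves
  the concordance denominator.  Truth sites whose stated reference base
  contradicts the genome are excluded with a warning.
* **Call-set comparison** (shared / exclusive, SNV vs indel) matches on
  exact (seq, pos, ref, alt) after normalization — shared-base trimming
  and left-alignment — so representation differences do not inflate
  exclusives.  Normalization is oracle-tested by haplotype
  reconstruction: two representations normalize to the same key iff they
  edit the reference identically.
* **QC cascade** for discordant/exclusive calls, fixed precedence:
  QD < 5 → `low_qd`; two-sided Fisher exact p < 0.01 on the
  ref/alt × fwd/rev table → `strand_bias` (a Fisher test is used because
  the production caller's bias statistic is not reproducible here, and no
  particular statistic is canonical); supporting depth < 10 → `low_depth`;
  ≥ 5 homologous loci → `homologous`; else `good`.  Homology counting
  takes the 101 bp window around the site (flank 50) and counts other
  loci, both strands, matching with ≤ 5 % mismatches (ungapped,
  pigeonhole-seeded, verified by Hamming distance; oracle: exhaustive
  sliding-window scan).

## Simulator

The simulator generates the structures the workflow's claims depend on,
with truth carried in read names (reference-coordinate source locus — the
simplest auditable channel):

* a random genome with non-overlapping planted gene models, written as
  refFlat + gene list;
* **paralogs**: near-identical copies of a target gene planted elsewhere,
  per-base mutated to a given identity (or, for exact accounting, with a
  substitution every N bp), inside or outside the target set.  Off-target
  paralogs are what make step 2 matter;
* diploid SNVs and 1–10 bp indels (het/hom equiprobable, ≥ 12 bp apart so
  truth records stay left-normalized and independent), applied to two
  haplotype sequences with exact coordinate maps back to the reference;
* paired-end reads: fragments uniform over a uniformly chosen haplotype,
  lengths from a configurable model (default normal, mean 397 bp, sd 80,
  truncated to [250, 700] — a standard short-insert paired-end design),
  100 bp mates, uniform substitution errors (default 0.001), flat quality
  strings at the phred of the error rate.  Flat qualities are a
  simplification; the workflow logic under test is insensitive to quality
  shape.

What the simulator does *not* emulate — platform error profiles, indel
sequencing errors, PCR duplicates, GC and coverage bias, real repeat
structure beyond the planted paralogs — bounds what passing tests show:
they validate the workflow's selection/correction/accounting logic and the
callers' statistics under clean assumptions, not performance on real
instrument data.

## Study scale and fixed conditions

The demonstration study (acceptance tests and `scripts/acceptance.py`)
uses a 100 kb genome, 10 target genes, two off-target paralogs at 95 %
identity, 30× coverage and error rate 0.001 — rich enough to contain
forced alignments, relocations and a 200-site truth panel while keeping a
desk-scale runtime.  The relocation-accounting fixture uses a 60 kb
genome, a paralog with one substitution every 30 bp (every 100 bp read
diverges from the source, yet always leaves a clean 21-mer seed and stays
within the 5 % edit budget), point fragment length 300 and error-free
reads, so the planted paralog fraction is recovered exactly up to binomial
noise.

## Numerical and degenerate-input choices

* All randomness flows from one integer seed (numpy PCG64); same seed ⇒
  byte-identical FASTA/FASTQ/VCF/JSON outputs.
* Alignment ties: lowest (sequence name, position), forward before
  reverse — total order, no RNG in the aligner.
* Fisher exact on an all-zero table returns p = 1; truth panels reject
  non-ACGT genotypes; empty region lists produce empty (warned) outputs;
  an empirical fragment model with no samples is an error.
* Caller QUAL is floored at 0 and rounded to 2 decimals; QD is derived,
  not stored, and round-trips through VCF to 2 decimals.
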