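# Methods

## ORF definition and density survey

An sORF is an ATG-initiated reading frame on the forward (sense) strand of
a mature transcript, read in-frame to the first stop codon (TAA/TAG/TGA),
encoding at least `min_aa` residues (default 10, stop excluded). Codons
containing an ambiguous base (N) never act as start or stop and translate
to X. Two counting modes are exposed because "number of ORFs" is ambiguous
when several in-frame ATGs share a stop: `maximal` (default) counts one
ORF per (frame, stop) pair, initiated at the 5′-most ATG; `all` counts
every qualifying ATG. The default avoids inflating density comparisons
with ATG runs; `all` supports sensitivity analysis and alternative-start
annotation. ORFs must terminate at an in-transcript stop by default; an
`allow_open` flag admits stop-less 3′-truncated ORFs.

Density is ORFs per kilobase computed per transcript and compared across
RNA classes as distributions (box-plot semantics), not pooled per class:
Kruskal–Wallis globally, pairwise two-sided Mann–Whitney with Bonferroni
correction over all pairs. Classes with fewer than two transcripts are
dropped with a warning. When every observation is identical the tests are
reported as p = 1 (all-ties convention).

## Three-frame translation and peptide matching

Translation uses the standard nuclear code (Biopython's table) with '\*'
at stops. Peptide matching is exact, case-insensitive substring
containment within stop-free segments of a frame translation — a peptide
spanning a stop cannot be a single translation product. No mismatches and
no I/L equivalence are allowed: fuzziness would change counts in ways that
cannot be validated against planted truth. The minimum peptide length for
matching defaults to 7 aa (shorter peptides match spuriously at these
transcriptome sizes); it is a flag, not a constant. Every occurrence is
reported, sorted by (transcript, frame, offset, peptide id). In pri-miR
summaries, a peptide hitting several pri-miRs counts once in the distinct
peptide total and once per transcript in per-transcript counts; both
numbers are reported to avoid ambiguity.

## miORF annotation

For a pri-miR with a known pre-miR interval, the candidate miORF is the
longest ORF lying wholly 5′ of the hairpin, where "wholly 5′" means the
stop codon ends at or before the pre-miR start — processing separates the
two regions, so an ORF crossing the hairpin boundary is not a candidate.
Equal lengths break 5′-most (first translated under scanning). Downstream
in-frame ATGs sharing the stop are reported as alternative starts
(rank, residual length), the ATG1/ATG2 pattern.

Initiation-context scoring is a weight-normalized consensus match over
positions −4..−1 and +4 relative to the A of the ATG, defaulting to a
Cavener-style Drosophila consensus ((C/A)AA(A/C)ATG G) with −3 weighted
double. A context is "favorable" when the score reaches the threshold
(default 0.5) and the −3 base is in the preferred set. This is a heuristic
annotation — favorability of any particular natural context is ultimately
an experimental property — and both matrix and threshold are configurable.

Variants are single-base substitutions applied with a reference-base
check; all annotation is recomputed from scratch on the new sequence.
When the candidate keeps its start, the C-terminal truncation is reported
as (original − new) residue count; a changed start reports `start_lost`
rather than a truncation length.

## TMM normalization and the simplified NB test

TMM follows the canonical recipe: the reference library is the one whose
upper-quartile relative abundance is closest to the across-sample mean;
per-library M-values (log2 relative-abundance ratios against the
reference) are trimmed 30% two-sided and A-values 5% two-sided; kept
M-values are combined with inverse asymptotic-variance weights; factors
are rescaled to geometric mean 1. The implementation is cross-checked in
the test suite against Bioconductor edgeR's `calcNormFactors` on a small
matrix and against an independent trim-and-weight oracle.

The differential-expression test is deliberately a documented simplified
negative-binomial framework, not a re-implementation of any reference
tool: counts are scaled by effective library size (library total × TMM
factor, normalized to geometric mean 1); per-gene dispersion φ in
Var = μ + φμ² is estimated by a within-group moment estimator pooled
across the two groups, then shrunk toward the common dispersion (the mean
over expressed genes) with fixed weight 0.7 on the common value; the Wald
statistic is the difference of natural-log normalized group means over its
delta-method NB standard error, referred to the standard normal. log2
fold changes use a pseudo-mean offset of 0.5 normalized counts so
zero-containing genes stay finite. Genes with all-zero counts in both
groups are assigned p = 1 and logFC = 0. The test is validated by
calibration, not by gene-by-gene agreement with any package: under the
null its type-I error at 0.05 stays within binomial 3σ for 2,000 genes,
and at the planted |log2FC| = 1.5, dispersion 0.1, five replicates per
group its sensitivity at q ≤ 0.05 exceeds 0.9 (a bound computed once by
simulation and frozen in the tests).

Gene calling uses BH-adjusted q ≤ 0.05 (inclusive) and, optionally, a
strict linear fold-change cutoff (|FC| > threshold), matching the
boundary semantics stated for each. Partitioning reports A-only / B-only /
shared counts with direction breakdowns and percentages relative to each
condition's regulated set. Heatmap preparation standardizes each row to
mean 0 and sample (n−1) standard deviation 1, with constant rows mapped
to zero.

## Cross expectations and measurement statistics

Cross schemes hold parental genotypes as per-locus unordered allele
pairs. Gametes are enumerated with equal segregation and independent
assortment; progeny genotype probabilities are exact rationals; genotypes
matching any lethal pattern (balancer homozygotes being the canonical
case) are removed before renormalization; classes aggregate via an
ordered pattern map. Lethality is expressed as data, not hard-coded, so
arbitrary deletion/knock-in crosses are expressible.

Progeny goodness-of-fit uses an exact two-sided binomial for two classes —
exact and conservative at the tens-of-crosses scale where these counts
arise — and chi-square otherwise, falling back to an exact multinomial
(summing outcomes no more likely than observed) when any expected count
is below 5 and the enumeration is small (n ≤ 60, ≤ 4 classes).

The measurement battery follows the standard decision tree: per-group
D'Agostino–Pearson normality (requires n ≥ 8; smaller groups force the
nonparametric branch, which is recorded in the report), then either
one-way ANOVA gated by Bartlett's equal-variance test with Bonferroni
pairwise t-tests, or Kruskal–Wallis with Bonferroni-adjusted pairwise
Mann–Whitney tests; with exactly two groups the global test is the
pairwise one. Bonferroni is used in the nonparametric branch to mirror
the parametric one. Every intermediate p-value and the branch taken are
returned. Group summaries report mean ± s.e.m. (sample sd/√n; undefined
at n = 1).

## Synthetic-data generator

The generator defines the study conditions every validation runs under.

**Transcriptome.** Five classes with per-class counts (CDS 40, 5′UTR 60,
3′UTR 60, lncRNA 50, pri-miR 50) and length ranges typical of each class
(e.g. 5′UTRs 150–600 nt, pri-miRs 500–1,500 nt). Background sequence is
i.i.d. uniform ACGT with an 11-nt cassette carrying stop codons in all
three frames injected every 30 nt, so spurious ≥ 10-aa ORFs are rare and
the planted set is close to the detectable set — this keeps recall tests
sharp. ORFs (uniform 10–40 aa, sense codons excluding internal ATG) are
planted at Poisson rates per kb chosen to reproduce the qualitative
class ordering the survey is meant to detect: CDS 4.0, lncRNA 2.0,
pri-miR 2.0, both UTRs 0.5. pri-miR transcripts carry an 80-nt pre-miR
interval at 70% of their length; planted ORFs are confined 5′ of it, at
least one per transcript when the class rate is positive (when the rate
is zero, none are planted and the interval is still annotated).

**Peptides.** 200 peptides by default, half drawn as exact substrings
(7–17 aa) of planted-ORF peptides, half decoys produced by residue
shuffling with rejection sampling against all three-frame translations of
all transcripts, so decoy labels are correct by construction.

**Counts.** Log-normal relative abundances over 2,000 genes, library
sizes uniform in 0.8–1.2 M, NB dispersion 0.1, five replicates in each of
three conditions (ctrl and two treatments A and B). Planted DE fractions
of the gene universe are 6.0% A-specific, 7.6% B-specific and 2.4%
shared, so the shared share of B's planted set is 48/200 = 24% — the
co-regulated fraction the partition pipeline is asked to recover — with
|log2FC| = 1.5 and a random sign per gene (shared genes shift with the
same sign in both treatments).

**Progeny and phenotypes.** Progeny counts are multinomial draws from the
scheme's expected fractions reweighted by per-class relative viability.
Phenotypes are Normal(10 + shift, 1) in arbitrary units, with a scaled
t(3) option for heavy-tailed noise.

All randomness flows from `numpy.random.default_rng` seeded per simulator
from the config seed; identical (seed, config) reproduces outputs
byte-for-byte, and emitted files carry the seed and a config hash in
their metadata lines.

**What the generator does not emulate:** raw reads, ribosome footprints
and their offsetting, alignment and quantification artifacts, splicing,
gene–gene correlation in counts, per-gene dispersion trends, linkage,
meiotic drive or incomplete penetrance. Passing tests therefore
demonstrate correctness of the analysis logic under the stated generative
model, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Simulation-backed checks use 2,000 genes × 15 samples and a ~260-
transcript transcriptome; recovery statistics average 20 seeds and survey
patterns 10 seeds — sizes at which the targeted effects are
well-resolved while the full suite stays fast. Percentages in partition
summaries are relative to each condition's regulated set and are NaN when
that set is empty. TMM factors equal 1 when no finite M-values survive
trimming or when all |M| < 1e−6. BH adjustment is the standard step-up
via statsmodels, verified against a brute-force oracle. Exact cross
fractions use `fractions.Fraction` end to end; rounding happens only at
reporting time.

## Known limitations

- Forward-strand, ATG-initiated ORFs only; near-cognate starts (CTG/GTG)
  are out of scope for the survey definition.
- The NB test is a calibrated simplification; it does not reproduce any
  reference tool's per-gene statistics and is not meant to.
- The context score ranks initiation contexts plausibly but its threshold
  is a heuristic, not an experimentally derived constant.
- Pre-miR intervals are taken as given annotation; hairpin processing
  sites are not predicted.
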