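# Methods

## Pool-seq model and the sex-patterned SNP signature

A pool-seq experiment sequences one equimolar DNA pool per sex. Allele
frequencies are estimated from read counts, not genotypes, so every
statistic here is a function of the two per-pool frequency estimates. A
fully sex-linked allele lies on the sex-limited haplotype (Y in an XY
system, W in a ZW system): every heterogametic individual carries exactly
one copy, so its expected frequency is 0.5 in the heterogametic pool and 0
in the homogametic pool. Classification thresholds (fixed: frequency < 0.1
in one pool; polymorphic: within [0.3, 0.7] in the other) are wide enough
to absorb binomial read sampling at moderate depth and the dilution caused
by a sex system segregating at less than full frequency. The polymorphic
interval is treated as closed and the fixation threshold as strict, so
boundary behaviour is exactly testable.

## F_ST estimator

Published pool-seq sex scans rarely print their estimator, so the package
commits to the simplest one consistent with two-pool frequency data:
Wright's F_ST = (H_T − H̄_S)/H_T with H = 2p(1−p) and the pools weighted
equally, defined as 0 when H_T = 0. It is bounded in [0, 1], symmetric in
the pools, equals 0 at equal frequencies and 1 at a fixed difference.
Algebraically H_T − H̄_S = (p_M − p_F)²/2, which the tests use as an
independent oracle. No sample-size (Weir–Cockerham-style) correction is
applied: pool read depth, not individual count, is the sampling unit, and
the statistic is used as a ranking/visualisation track rather than an
estimator of a population parameter.

## Windowing and the automated sex-system call

Windows are non-overlapping 100-kb tiles, 0-based half-open in memory and
in BED output; site TSVs are 1-based. The top fraction (default 1%) is
taken over anchored sequences only, mirroring the practice of excluding
unplaced contigs from the denominator; exactly ceil(0.01·N) windows are
flagged, with ties at the boundary broken by (chrom, start) for
reproducibility. log2(XY:ZW) density ratios use a pseudocount of 1 in both
numerator and denominator so zero-count windows remain defined.

Kruskal–Wallis (tie-corrected, chi-square approximation on k−1 df) is
delegated to scipy; Dunn's post hoc z-statistics use the pooled
tie-corrected rank variance S = N(N+1)/12 − Σ(t³−t)/(12(N−1)) and are
Benjamini–Hochberg adjusted across pairs.

The sex-system call automates what is usually done by inspection, with
three exposed thresholds chosen a priori:

- **background rule** — a flagged window supports a call only if its count
  exceeds the Poisson(μ_bg) quantile at 1 − 0.01/N_anchored, where μ_bg is
  the mean count of non-flagged anchored windows. This caps the chance
  that a null scan produces any supporting window at roughly 1%.
- **plurality floor** — the called chromosome must hold ≥10% of all
  flagged windows, else the call is `none`.
- **heterogamety majority** — XY (ZW) requires more than 2/3 of the
  supporting windows on the called chromosome to have n_XY > n_ZW
  (n_ZW > n_XY); otherwise `mixed`, which covers chromosomes carrying
  coexisting XY and ZW signals.

## K-mer analysis

K-mers (default k = 22) are stored canonically (lexicographic min of k-mer
and reverse complement), making all comparisons strand-agnostic. A k-mer
is sex-specific when seen at least twice in the focal sex's pool and never
in the other pool; the ≥2 floor is the minimal guard against singleton
k-mers created by sequencing error, and a constructed fixture in the tests
shows exactly how single-error reads leak through at a floor of 1. Shared
origin between populations is inferred from the intersection of their
sex-specific sets; placement on a reference uses exact canonical matching
(a 1-mismatch mode enumerates the 3k substitution neighbours per query),
which for short perfect queries behaves like an alignment search without
the dependency.

## Recruitment statistics

The Poisson fit uses mean = events/categories and compares the observed
histogram of per-chromosome occurrence classes with Poisson expectations
whose final class absorbs the upper tail; tail classes are pooled upward
until the last expectation is ≥1, and df = bins − 2 (one df for the
estimated mean). The exact published binning for such tables is typically
unprinted, so the package reports χ², df and p together and treats
"non-rejection" as the reproducible conclusion.

The Monte Carlo null draws n_events chromosomes per replicate with
probability proportional to chromosome size; the raw p for a focal
chromosome is the proportion of replicates with a count ≥ the observed
count (an add-one variant is available by flag), and Bonferroni multiplies
by the number of focal tests (default: the number of focal chromosomes).
The bundled size table is an explicitly synthetic approximation of the
cichlid karyotype — 21 autosomes between 31.5 and 41.5 Mb, LG07 at 70.5 Mb
(about twice the mean), and the unpaired B chromosome assigned the mean
size (excludable by flag). Users with exact assembly lengths should supply
them; the qualitative LG05-excess / LG07-non-excess contrast is insensitive
to the approximation.

**Calibration of discrete Monte Carlo p-values.** The focal count is
integer-valued, so the plain tail-proportion p is superuniform with atoms
as large as ~0.27; demanding that it be exactly uniform would reject any
correct implementation. The calibration test therefore uses the standard
randomized p-value u = (n_gt + U·(n_eq + 1))/(n_reps + 1), which is exactly
Uniform(0, 1) when the observed table is itself drawn from the null, and
additionally checks superuniformity of the plain p. The reported p-value
is always the plain (or add-one) proportion.

Turnover rate is turnovers divided by summed branch length in MY. The
subtree selector sums the edges spanning the selected taxa plus the stem
edge of their most recent common ancestor (the global root edge is never
counted). The bundled Newick tree is a synthetic stand-in with round
branch lengths (total 26.0 MY; the focal-genus subtree 9.8 MY), not an
estimated phylogeny; real analyses should pass their own dated tree.

## Synthetic data: what it does and does not emulate

Generators are deterministic given a seed and emit truth tables so
sensitivity/specificity are exactly computable.

Pooled counts: background SNPs take one population frequency per site,
drawn Uniform(0.05, 0.95) (common-variant ascertainment), shared by the
sexes; pool frequencies then differ only via binomial sampling of 2N
chromosomes per pool and of reads onto alleles. Sex-linked sites ride the
sex-limited haplotype; with system frequency φ < 1 the number of
heterogametic individuals governed by the system is Binomial(N, φ), so the
expected pool frequency is 0.5·φ. Read depth is Poisson (default 50×) and
sequencing error substitutes each read's base uniformly among the other
three at rate 0.002. The default genome is three 5-Mb chromosomes with
background density 1 SNP/kb — small enough for fast tests, large enough
for ~150 windows. The default planted region is 1 Mb with two strata
(7×10⁻³ and 2.5×10⁻⁴ sex-linked SNPs per bp, i.e. ~700 and ~25 per 100-kb
window, spanning the density range seen between old and recently emerged
systems). Not modelled: linkage/recombination structure, coalescent noise
among individuals, mapping artefacts, reference bias, copy-number
variation. Passing recovery tests therefore demonstrates the statistical
machinery, not robustness to alignment pathologies.

Sequence pools: the sex-limited segment is emitted as its own unassembled
source sequence (as a Y-specific insertion appears relative to a reference
lacking it), so a 1,000-bp segment contributes exactly 1000 − 22 + 1 = 979
specific 22-mers with no junction k-mers. Reads tile each source with a
fixed step and are emitted in ≥2 copies, mimicking the many identical
molecules of a pool and satisfying the ≥2 specificity floor; a random-
error mode exercises the floor itself.

## Problem sizes in tests and the acceptance script

End-to-end recovery uses 20 planted and 10 null replicates on the default
3×5-Mb genome; Monte Carlo significance uses 10,000 replicates; KW
calibration 1,000 null scans of 5×30 windows; MC calibration 500 null
tables at 400 replicates each. These sizes give Monte Carlo standard
errors comfortably inside the asserted bounds while keeping the whole
suite under a minute.
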