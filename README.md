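# sexscan

Pooled-sequencing discovery of sex chromosomes, and statistics of how often
chromosomes are recruited into that role.

## The problem

In many fish lineages — African cichlids are the extreme case — the
sex-determining locus moves between chromosomes on timescales of a few
million years. A cheap way to find the current sex chromosome of a
population is pool-seq: sequence one DNA pool of males and one of females,
estimate allele frequencies from read counts, and look for the signature of
a sex-limited (Y or W) haplotype. `sexscan` implements that scan end to end,
plus the comparative statistics used to ask whether some chromosomes become
sex chromosomes more often than chance.

## What it computes

**Per-site differentiation** (`sexscan.pool_diff`). For each variable site
with adequate depth in both pools, per-allele pool frequencies and Wright's
two-population fixation index

F_ST = (H_T − H̄_S) / H_T,  H = 2p(1−p),

with the pools equally weighted (F_ST ≡ 0 when H_T = 0). An allele is
**XY-patterned** when it is effectively fixed out of the female pool
(f_F < 0.1) and polymorphic in the male pool (0.3 ≤ f_M ≤ 0.7) — the
expectation for a Y-linked allele at frequency ½ among male haplotypes —
and **ZW-patterned** in the mirror case.

**Window scan** (`sexscan.windows`). Sex-patterned SNPs are counted in
100-kb tiles; the top 1% of anchored windows by count localise the
sex-determining region; log2((n_XY+1)/(n_ZW+1)) per window summarises the
heterogametic pattern; a Kruskal–Wallis test with Dunn's post hoc
(Benjamini–Hochberg adjusted) tests heterogeneity among chromosomes; and
`call_sex_system` turns the flagged windows into an automated call
(chromosome, XY/ZW/mixed/none).

**K-mer sharing** (`sexscan.kmers`). Canonical 22-mers are tabulated per
pool; k-mers seen ≥2× in one sex's pool and never in the other's are
sex-specific; intersecting the sex-specific sets of two populations, and
placing the intersection on a reference by exact match, tests whether
syntenic systems share a single origin.

**Recruitment statistics** (`sexscan.recruitment`). Given a tabulation of
independent sex-chromosome origins per linkage group (the bundled table has
51 events over 23 categories), the module fits a Poisson (mean 51/23 ≈ 2.2
events/chromosome) with a chi-square goodness-of-fit test, runs a
chromosome-size-weighted Monte Carlo null for focal chromosomes with
Bonferroni correction, and estimates turnover rates as turnovers per million
years of summed branch length on a dated tree.

**Synthetic data** (`sexscan.simulate`). Deterministic, seeded generators
for every input: pooled counts with a planted sex-determining region
(binomial read sampling at Poisson depth, sequencing error, multiple strata
of differing SNP density, optional reduced system frequency), read sets
carrying a sex-limited insertion (shared or independent between
populations), and recruitment tables drawn from the size-weighted null.

## Worked example

```bash
sexscan simulate-counts --seed 4 --outdir demo          # plants XY on chr2
sexscan classify demo/pooled_counts.tsv --out demo/cls.tsv
sexscan scan demo/cls.tsv demo/chrom_sizes.tsv --outdir demo
sexscan recruit --seed 1 --n-reps 10000 --out demo/recruit.json
sexscan turnover --n-turnovers 6 --out demo/turnover.json
```

The scan step prints

```
call: XY on chr2 (2 supporting windows)
```

meaning both flagged top-1% windows exceed the genome-wide background
threshold, sit on chr2, and are XY-patterned — the planted system. The
recruit step prints

```
Poisson mean 2.217, GOF p 0.839 -> demo/recruit.json
```

the per-chromosome recruitment mean and the non-rejection of the Poisson
fit; the JSON adds the size-weighted Monte Carlo results (at 10,000
replicates, Bonferroni p ≈ 0.010 for LG05 with 7 observed events, ≈ 0.48
for LG07 with 6 — LG07 is roughly twice the size, so its excess is
expected). The turnover step prints

```
6 turnovers / 26.00 MY = 0.23 per MY
```

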