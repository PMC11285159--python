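"""Synthetic pool-seq data with planted sex-determining regions.

Everything the pipeline consumes can be generated here with known ground
truth: pooled allele-count tables (background SNPs shared between the
sexes plus a planted sex-linked region), read-like sequence sets carrying a
sex-limited insertion for the k-mer analysis, and recruitment tables drawn
from a size-weighted null.

The pooled-count model: each background SNP has one population frequency
shared by both sexes; pool frequencies then differ only through the
binomial sampling of individuals into the pools and of reads onto alleles.
A sex-linked site carries its allele on the sex-limited haplotype, so its
expected frequency is 0.5 * system_frequency in the heterogametic pool and
0 (plus sequencing error) in the other. Per-site read depth is Poisson;
sequencing error substitutes reads uniformly among the other three bases.
All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool_diff import BASES

_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: default genome: three 5-Mb chromosomes (desk-scale but window-rich)
DEFAULT_GENOME = {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000}
DEFAULT_BACKGROUND_SNP_DENSITY = 1e-3  # 1 SNP per kb


@dataclass(frozen=True)
class Stratum:
    """Sub-interval of a sex-determining region with its own density of
    sex-linked SNPs (per bp). Distinct strata emulate successive
    recombination-suppression events of different ages."""

    start: int
    end: int
    snp_density: float


@dataclass
class SexSystemSpec:
    """A planted sex-determining region.

    ``system_frequency`` is the fraction of the heterogametic sex whose
    phenotypic sex is governed by this system (< 1 emulates a second,
    unsampled system segregating in the population, which dilutes the pool
    signal). Default strata split the region into an older half with a high
    density of sex-linked SNPs (~700 per 100 kb) and a younger half with a
    low density (~25 per 100 kb).
    """

    chrom: str
    start: int
    end: int
    heterogamety: str = "XY"  # "XY" or "ZW"
    system_frequency: float = 1.0
    strata: list[Stratum] = field(default_factory=list)

    def __post_init__(self):
        if self.heterogamety not in ("XY", "ZW"):
            raise ValueError("heterogamety must be XY or ZW")
        if not 0 < self.system_frequency <= 1:
            raise ValueError("system_frequency must be in (0, 1]")
        if not self.strata:
            mid = (self.start + self.end) // 2
            self.strata = [Stratum(self.start, mid, 7e-3),
                           Stratum(mid, self.end, 2.5e-4)]
        for s in self.strata:
            if not (self.start <= s.start < s.end <= self.end):
                raise ValueError("stratum outside the region")


@dataclass(frozen=True)
class PoolDesign:
    """Pooled sequencing design (defaults match a typical family pool)."""

    n_males: int = 25
    n_females: int = 24
    depth: float = 50.0  # mean reads per site per pool
    error_rate: float = 0.002  # per-base substitution rate

    def __post_init__(self):
        if min(self.n_males, self.n_females) < 1 or self.depth <= 0:
            raise ValueError("pool design values must be positive")


def default_sex_system(chrom: str = "chr2", start: int = 2_000_000,
                       end: int = 3_000_000,
                       heterogamety: str = "XY") -> SexSystemSpec:
    """A 1-Mb two-stratum system on the middle chromosome of the default
    genome."""
    return SexSystemSpec(chrom, start, end, heterogamety)


def _sample_positions(rng, lo: int, hi: int, density: float) -> np.ndarray:
    """Distinct 1-based positions in (lo, hi] at the given per-bp rate."""
    span = hi - lo
    n = rng.poisson(span * density)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(rng.integers(lo + 1, hi + 1, size=n))


def _apply_errors(counts: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Substitute reads uniformly to the other three bases at ``error_rate``."""
    if error_rate <= 0:
        return counts
    out = counts.copy()
    for b in range(4):
        n_err = rng.binomial(counts[:, b], error_rate)
        out[:, b] -= n_err
        dest = [j for j in range(4) if j != b]
        redistributed = rng.multinomial(n_err, [1 / 3] * 3)
        for k, j in enumerate(dest):
            out[:, j] += redistributed[:, k]
    return out


def _pool_counts(rng, n_sites: int, alt_freq: np.ndarray, mean_depth: float,
                 ref_idx: np.ndarray, alt_idx: np.ndarray,
                 error_rate: float) -> np.ndarray:
    depth = rng.poisson(mean_depth, size=n_sites)
    alt_reads = rng.binomial(depth, alt_freq)
    ref_reads = depth - alt_reads
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    np.add.at(counts, (np.arange(n_sites), ref_idx), ref_reads)
    np.add.at(counts, (np.arange(n_sites), alt_idx), alt_reads)
    return _apply_errors(counts, error_rate, rng)


def simulate_pooled_counts(genome=None, sex_systems=None,
                           design: PoolDesign = PoolDesign(),
                           background_snp_density: float =
                           DEFAULT_BACKGROUND_SNP_DENSITY,
                           seed: int | None = None):
    """Generate a pooled allele-count table plus its truth table.

    Parameters
    ----------
    genome
        Mapping chromosome -> length (default three 5-Mb chromosomes).
    sex_systems
        A :class:`SexSystemSpec`, a list of them (two specs on one
        chromosome emulate coexisting XY and ZW systems), or None for a
        null genome with background SNPs only.
    design
        Pool sizes, mean depth and error rate.
    background_snp_density
        Background SNPs per bp, shared between the sexes.
    seed
        Mandatory RNG seed.

    Returns
    -------
    (counts, truth): ``counts`` has columns chrom, pos, ref, A_m..T_f;
    ``truth`` has chrom, pos, true_label in {XY, ZW, background} and the
    true pool allele frequencies.
    """
    if seed is None:
        raise ValueError("seed is required")
    genome = dict(DEFAULT_GENOME if genome is None else genome)
    if sex_systems is None:
        sex_systems = []
    elif isinstance(sex_systems, SexSystemSpec):
        sex_systems = [sex_systems]
    for spec in sex_systems:
        if spec.chrom not in genome:
            raise ValueError(f"region chromosome {spec.chrom} not in genome")
        if not (0 <= spec.start < spec.end <= genome[spec.chrom]):
            raise ValueError("region outside chromosome bounds")

    rng = np.random.default_rng(seed)
    chroms, positions, labels, true_fm, true_ff = [], [], [], [], []

    # background SNPs: one shared population frequency per site
    n2m, n2f = 2 * design.n_males, 2 * design.n_females
    for chrom in genome:
        pos = _sample_positions(rng, 0, genome[chrom], background_snp_density)
        p = rng.uniform(0.05, 0.95, size=len(pos))
        fm = rng.binomial(n2m, p) / n2m  # individual sampling into the pools
        ff = rng.binomial(n2f, p) / n2f
        chroms.append(np.repeat(chrom, len(pos)))
        positions.append(pos)
        labels.append(np.repeat("background", len(pos)))
        true_fm.append(fm)
        true_ff.append(ff)

    # sex-linked SNPs: allele rides the sex-limited haplotype
    for spec in sex_systems:
        n_het = design.n_males if spec.heterogamety == "XY" else design.n_females
        n_governed = rng.binomial(n_het, spec.system_frequency)
        het_freq = n_governed / (2 * n_het)
        for stratum in spec.strata:
            pos = _sample_positions(rng, stratum.start, stratum.end,
                                    stratum.snp_density)
            chroms.append(np.repeat(spec.chrom, len(pos)))
            positions.append(pos)
            labels.append(np.repeat(spec.heterogamety, len(pos)))
            if spec.heterogamety == "XY":
                true_fm.append(np.full(len(pos), het_freq))
                true_ff.append(np.zeros(len(pos)))
            else:
                true_fm.append(np.zeros(len(pos)))
                true_ff.append(np.full(len(pos), het_freq))

    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions).astype(np.int64)
    label_arr = np.concatenate(labels)
    fm_arr = np.concatenate(true_fm)
    ff_arr = np.concatenate(true_ff)

    # drop background sites colliding with a sex-linked site
    key = pd.Series(chrom_arr).str.cat(pos_arr.astype(str), sep=":")
    is_linked = label_arr != "background"
    dup = key.duplicated(keep=False).to_numpy() & ~is_linked
    keep = ~dup
    chrom_arr, pos_arr = chrom_arr[keep], pos_arr[keep]
    label_arr, fm_arr, ff_arr = label_arr[keep], fm_arr[keep], ff_arr[keep]

    n_sites = len(pos_arr)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    counts_m = _pool_counts(rng, n_sites, fm_arr, design.depth, ref_idx,
                            alt_idx, design.error_rate)
    counts_f = _pool_counts(rng, n_sites, ff_arr, design.depth, ref_idx,
                            alt_idx, design.error_rate)

    counts = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr,
                           "ref": np.array(BASES)[ref_idx]})
    for i, b in enumerate(BASES):
        counts[f"{b}_m"] = counts_m[:, i]
    for i, b in enumerate(BASES):
        counts[f"{b}_f"] = counts_f[:, i]
    truth = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr,
                          "true_label": label_arr,
                          "true_freq_male": fm_arr,
                          "true_freq_female": ff_arr,
                          "alt": np.array(BASES)[alt_idx]})
    order = np.lexsort((pos_arr, chrom_arr))
    return (counts.iloc[order].reset_index(drop=True),
            truth.iloc[order].reset_index(drop=True))


# ---------------------------------------------------------------------------
# sequence-level simulation for the k-mer analysis
# ---------------------------------------------------------------------------

@dataclass
class PoolSequences:
    """Read sets for one population plus the sequences behind them."""

    reference: dict  # chrom -> sequence (sex-limited insertion NOT included)
    insertion: str  # the sex-limited segment ("" when none was planted)
    heterogamety: str
    male_reads: list  # [(name, sequence), ...]
    female_reads: list


def _random_seq(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _tile_reads(name: str, seq: str, read_length: int, step: int,
                copies: int, error_rate: float, rng) -> list:
    if len(seq) < read_length:
        starts = [0]
        read_length = len(seq)
    else:
        starts = list(range(0, len(seq) - read_length + 1, step))
        last = len(seq) - read_length
        if starts[-1] != last:
            starts.append(last)
    reads = []
    for c in range(copies):
        for s in starts:
            read = seq[s:s + read_length]
            if error_rate > 0:
                arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
                for i in hit:
                    choices = [b for b in b"ACGT" if b != arr[i]]
                    arr[i] = choices[rng.integers(0, 3)]
                read = arr.tobytes().decode()
            reads.append((f"{name}|c{c}|p{s}", read))
    return reads


def simulate_pool_sequences(chrom_lengths=None, insertion_length: int = 1000,
                            heterogamety: str = "XY", read_length: int = 150,
                            step: int | None = None, copies: int = 2,
                            error_rate: float = 0.0,
                            insertion_seq: str | None = None,
                            seed: int | None = None) -> PoolSequences:
    """Simulate male/female read sets with a sex-limited insertion.

    The insertion is modelled as a Y- (or W-) specific segment absent from
    the reference and from the homogametic pool; reads tile every source
    sequence with the given step and are emitted ``copies`` times (so every
    k-mer of a source appears at least ``copies`` times, mimicking the many
    identical molecules of a pool). Passing ``insertion_seq`` plants the
    same segment in a second population (shared origin); omitting it draws
    a fresh random segment (independent origin). ``insertion_length`` 0
    plants nothing.
    """
    if seed is None:
        raise ValueError("seed is required")
    if heterogamety not in ("XY", "ZW"):
        raise ValueError("heterogamety must be XY or ZW")
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 20_000, "chr2": 20_000, "chr3": 20_000}
    reference = {c: _random_seq(rng, n) for c, n in chrom_lengths.items()}
    if insertion_seq is not None:
        insertion = insertion_seq
    elif insertion_length > 0:
        insertion = _random_seq(rng, insertion_length)
    else:
        insertion = ""
    if step is None:
        step = max(1, read_length // 2)

    shared_sources = list(reference.items())
    limited_sources = [("sexlimited", insertion)] if insertion else []
    het_reads, hom_reads = [], []
    for name, seq in shared_sources + limited_sources:
        het_reads.extend(_tile_reads(name, seq, read_length, step, copies,
                                     error_rate, rng))
    for name, seq in shared_sources:
        hom_reads.extend(_tile_reads(name, seq, read_length, step, copies,
                                     error_rate, rng))
    if heterogamety == "XY":
        male_reads, female_reads = het_reads, hom_reads
    else:
        male_reads, female_reads = hom_reads, het_reads
    return PoolSequences(reference, insertion, heterogamety,
                         male_reads, female_reads)


def integrate_insertion(reference: dict, chrom: str, pos: int,
                        insertion: str) -> dict:
    """Reference with the sex-limited segment integrated at ``pos`` on
    ``chrom`` (for placement tests against a reference that carries the
    region)."""
    out = dict(reference)
    seq = out[chrom]
    out[chrom] = seq[:pos] + insertion + seq[pos:]
    return out


def simulate_recruitments(n_events: int, sizes: pd.DataFrame,
                          seed: int | None = None) -> pd.DataFrame:
    """Draw a recruitment table under the size-weighted null.

    Categories are drawn with probability proportional to chromosome size;
    counts sum to ``n_events``.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    probs = sizes["size"].to_numpy(dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n_events, probs)
    return pd.DataFrame({"chrom": sizes["chrom"].to_numpy(), "count": counts})
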