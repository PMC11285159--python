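"""Macro-evolutionary statistics of sex-chromosome recruitment.

Given a tabulation of how many times each chromosome has independently been
recruited as a sex chromosome across a clade, this module fits a Poisson
distribution to the per-chromosome occurrence counts (chi-square goodness of
fit with tail pooling), tests whether individual chromosomes are recruited
more often than expected under a chromosome-size-weighted Monte Carlo null
(Bonferroni corrected), and estimates turnover rates as turnovers divided by
summed phylogenetic branch length in millions of years (MY).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

RECRUITMENT_FIXTURE = "cichlid_sex_recruitments.tsv"
CHROM_SIZE_FIXTURE = "mzebra_chrom_sizes.synthetic.tsv"
TREE_FIXTURE = "basal_haplochromine_tree.synthetic.nwk"


def _data_path(name: str):
    return resources.files("sexscan.data").joinpath(name)


def load_recruitment_table(path=None) -> pd.DataFrame:
    """Load a recruitment table (columns ``chrom``, ``count``).

    With no path, returns the bundled tabulation of independent
    sex-chromosome origins per linkage group in East African cichlids
    (51 events over 23 categories including the B chromosome).
    """
    src = path if path is not None else _data_path(RECRUITMENT_FIXTURE)
    df = pd.read_csv(src, sep="\t", comment="#")
    df.columns = ["chrom", "count"]
    if (df["count"] < 0).any() or not np.issubdtype(df["count"].dtype, np.integer):
        raise ValueError("recruitment counts must be non-negative integers")
    return df


def load_chrom_sizes(path=None) -> pd.DataFrame:
    """Load a chromosome-size table (columns ``chrom``, ``size`` in bp).

    With no path, returns the bundled approximate reference karyotype
    (synthetic sizes; LG07 about twice the mean of the rest, B chromosome
    assigned the mean size).
    """
    src = path if path is not None else _data_path(CHROM_SIZE_FIXTURE)
    df = pd.read_csv(src, sep="\t", comment="#")
    df.columns = ["chrom", "size"]
    if (df["size"] <= 0).any():
        raise ValueError("chromosome sizes must be positive")
    return df


def default_tree_path():
    """Path to the bundled synthetic basal-haplochromine tree (branch
    lengths in MY; illustrative, not an estimated phylogeny)."""
    return _data_path(TREE_FIXTURE)


def poisson_mean(table: pd.DataFrame) -> float:
    """Mean recruitment events per chromosome (total events / categories)."""
    if len(table) == 0:
        raise ValueError("empty recruitment table")
    return float(table["count"].sum()) / len(table)


def poisson_expected(mean: float, n_categories: int,
                     max_count: int) -> np.ndarray:
    """Expected number of chromosomes per occurrence class 0..max_count.

    Class j < max_count gets n * pmf(j); the last class absorbs the upper
    tail P(X >= max_count), so the expectations sum exactly to
    ``n_categories``.
    """
    if mean < 0:
        raise ValueError("mean must be non-negative")
    j = np.arange(max_count + 1)
    expected = n_categories * stats.poisson.pmf(j, mean)
    expected[-1] = n_categories * stats.poisson.sf(max_count - 1, mean)
    return expected


def chisq_gof(observed, expected, ddof: int = 1):
    """Chi-square goodness of fit on pre-binned classes.

    df = bins - 1 - ddof (ddof=1 when the distribution mean was estimated
    from the data).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if len(observed) < 2:
        raise ValueError("need at least 2 bins")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = len(observed) - 1 - ddof
    if df < 1:
        raise ValueError("no degrees of freedom left after pooling")
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class PoissonFit:
    mean: float
    observed: np.ndarray  # per occurrence class, after pooling
    expected: np.ndarray
    chi2: float
    df: int
    pvalue: float


def poisson_gof(table: pd.DataFrame, mean: float | None = None,
                pool_min: float = 1.0) -> PoissonFit:
    """Fit a Poisson to per-chromosome occurrence counts and test fit.

    Builds the histogram of occurrence classes 0..max(count), computes
    Poisson expectations with the tail absorbed in the last class, then
    pools classes from the top down until the last expectation is at least
    ``pool_min``. df = bins - 2 (one df for the estimated mean).
    """
    est_mean = poisson_mean(table) if mean is None else float(mean)
    counts = table["count"].to_numpy()
    max_c = int(counts.max())
    observed = np.bincount(counts, minlength=max_c + 1).astype(float)
    expected = poisson_expected(est_mean, len(table), max_c)
    while len(expected) > 2 and expected[-1] < pool_min:
        expected = np.concatenate([expected[:-2], [expected[-2] + expected[-1]]])
        observed = np.concatenate([observed[:-2], [observed[-2] + observed[-1]]])
    chi2, df, p = chisq_gof(observed, expected, ddof=1)
    return PoissonFit(est_mean, observed, expected, chi2, df, p)


@dataclass
class MonteCarloFocal:
    chrom: str
    observed: int
    n_ge: int  # replicates with count >= observed
    n_gt: int  # replicates with count > observed
    n_reps: int
    p_raw: float
    p_bonferroni: float


def monte_carlo_recruitment(observed: pd.DataFrame, sizes: pd.DataFrame,
                            focal_chroms, n_events: int | None = None,
                            n_reps: int = 1000, n_tests: int | None = None,
                            seed: int | None = None, add_one: bool = False,
                            exclude=()) -> list[MonteCarloFocal]:
    """Size-weighted Monte Carlo test of recruitment excess.

    Each replicate draws ``n_events`` chromosomes with probability
    proportional to chromosome size; the raw p for a focal chromosome is the
    proportion of replicates whose count for that chromosome is at least the
    observed count (``add_one`` switches to the (r+1)/(n+1) estimator).
    Bonferroni multiplies by ``n_tests`` (default: number of focal
    chromosomes) and caps at 1.

    ``exclude`` drops categories (e.g. the B chromosome) from both the
    observed table and the null before sampling.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    obs = observed[~observed["chrom"].isin(exclude)]
    siz = sizes[~sizes["chrom"].isin(exclude)]
    size_map = dict(zip(siz["chrom"], siz["size"]))
    missing = set(obs["chrom"]) - set(size_map)
    if missing:
        raise ValueError(f"no size for categories: {sorted(missing)}")
    for chrom in focal_chroms:
        if chrom not in size_map:
            raise ValueError(f"focal chromosome {chrom} absent from size table")
    cats = list(obs["chrom"])
    probs = np.array([size_map[c] for c in cats], dtype=float)
    probs /= probs.sum()
    if n_events is None:
        n_events = int(obs["count"].sum())
    n_tests = len(focal_chroms) if n_tests is None else n_tests

    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_events, probs, size=n_reps)  # (n_reps, k)
    obs_map = dict(zip(obs["chrom"], obs["count"]))
    results = []
    for chrom in focal_chroms:
        i = cats.index(chrom)
        c = int(obs_map[chrom])
        n_ge = int(np.count_nonzero(draws[:, i] >= c))
        n_gt = int(np.count_nonzero(draws[:, i] > c))
        if add_one:
            p_raw = (n_ge + 1) / (n_reps + 1)
        else:
            p_raw = n_ge / n_reps
        results.append(MonteCarloFocal(
            chrom=chrom, observed=c, n_ge=n_ge, n_gt=n_gt, n_reps=n_reps,
            p_raw=p_raw, p_bonferroni=min(1.0, p_raw * n_tests)))
    return results


def randomized_null_pvalue(focal: MonteCarloFocal, rng) -> float:
    """Randomized Monte Carlo p-value for calibration checks.

    For a discrete test statistic the plain tail-proportion p is
    superuniform, not uniform. When the observed table is itself drawn from
    the null, u = (n_gt + U * (n_eq + 1)) / (n_reps + 1) with U ~ Uniform(0,1)
    and n_eq = n_ge - n_gt is exactly Uniform(0,1), which is the property a
    calibration test should check. The reported p-value is unaffected.
    """
    n_eq = focal.n_ge - focal.n_gt
    return (focal.n_gt + rng.uniform() * (n_eq + 1)) / (focal.n_reps + 1)


def sum_branch_lengths(tree, taxa=None) -> float:
    """Sum branch lengths (MY) over a tree or a selected subtree.

    ``tree`` is a dendropy Tree, a path, or a Newick string. With ``taxa``
    given, sums the edges of the spanning subtree connecting those taxa,
    plus the stem edge of their MRCA; the global root edge is always
    excluded. Raises if a selected edge lacks a length.
    """
    if not isinstance(tree, dendropy.Tree):
        src = str(tree)
        if "(" in src:
            tree = dendropy.Tree.get(data=src, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick",
                                     preserve_underscores=True)
    tree.is_rooted = True

    def _edge_length(node):
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise ValueError(f"edge above {label} has no branch length")
        return float(node.edge.length)

    root = tree.seed_node
    if taxa is None:
        nodes = [n for n in tree.preorder_node_iter() if n is not root]
        return sum(_edge_length(n) for n in nodes)

    taxa = set(taxa)
    leaves = [leaf for leaf in tree.leaf_node_iter()
              if leaf.taxon is not None and leaf.taxon.label in taxa]
    found = {leaf.taxon.label for leaf in leaves}
    if found != taxa:
        raise ValueError(f"taxa not in tree: {sorted(taxa - found)}")
    mrca = tree.mrca(taxa=[leaf.taxon for leaf in leaves])
    selected = set()
    for leaf in leaves:
        node = leaf
        while node is not mrca:
            selected.add(node)
            node = node.parent_node
    if mrca is not root:
        selected.add(mrca)  # stem edge of the selected clade
    return sum(_edge_length(n) for n in selected)


def turnover_rate(n_turnovers: int, branch_length_sum: float) -> float:
    """Sex-chromosome turnovers per million years."""
    if branch_length_sum <= 0:
        raise ValueError("branch length sum must be positive")
    if n_turnovers < 0:
        raise ValueError("turnover count must be non-negative")
    return n_turnovers / branch_length_sum
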