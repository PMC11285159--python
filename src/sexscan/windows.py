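"""Windowed genome scan over sex-patterned SNPs.

Classified XY/ZW SNP records are aggregated into non-overlapping 100-kb
windows; the top 1% of anchored windows by sex-patterned SNP count localise
the sex-determining region, the log2(XY:ZW) density ratio summarises which
heterogametic pattern dominates, and a Kruskal-Wallis test with Dunn's post
hoc (Benjamini-Hochberg adjusted) asks whether that ratio differs among
chromosomes. ``call_sex_system`` automates the final call of the sex
chromosome and its heterogamety.

Window coordinates are 0-based half-open (BED convention); site positions in
TSV input are 1-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

WINDOW_WIDTH = 100_000
#: pseudocount keeping log2(XY:ZW) finite for zero-count windows
LOG2_PSEUDOCOUNT = 1.0


@dataclass
class KruskalResult:
    H: float
    df: int
    pvalue: float


@dataclass
class SexSystemCall:
    """Automated call of the sex chromosome for one scan."""

    chrom: str | None
    heterogamety: str  # "XY" | "ZW" | "mixed" | "none"
    n_top_windows_on_chrom: int
    intervals: list = field(default_factory=list)  # (start, end) on chrom


def make_windows(chrom_sizes, width: int = WINDOW_WIDTH,
                 anchored=None) -> pd.DataFrame:
    """Tile each sequence with non-overlapping windows.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome -> length in bp (or a DataFrame with ``chrom``
        and ``size`` columns).
    width
        Window width in bp; the last window of a sequence may be shorter.
    anchored
        Optional mapping chromosome -> bool (or set of anchored names).
        Unlisted chromosomes default to anchored. Unanchored contigs are
        excluded from the top-percent denominator downstream.

    Returns
    -------
    DataFrame ``chrom, start, end, anchored`` with 0-based half-open
    coordinates; ceil(size/width) windows per sequence.
    """
    if isinstance(chrom_sizes, pd.DataFrame):
        chrom_sizes = dict(zip(chrom_sizes["chrom"], chrom_sizes["size"]))
    if not chrom_sizes:
        raise ValueError("empty chromosome size table")
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        size = int(size)
        if size <= 0:
            raise ValueError(f"non-positive size for {chrom}")
        if anchored is None:
            anch = True
        elif isinstance(anchored, (set, frozenset, list, tuple)):
            anch = chrom in anchored
        else:
            anch = bool(anchored.get(chrom, True))
        for start in range(0, size, width):
            rows.append((chrom, start, min(start + width, size), anch))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "anchored"])


def count_in_windows(classifications: pd.DataFrame,
                     windows: pd.DataFrame) -> pd.DataFrame:
    """Count XY and ZW SNP records per window.

    Records with label ``none`` are ignored; records on chromosomes absent
    from the window set are logged and excluded (reported via the
    ``n_unplaced`` DataFrame attribute). Assumes the windows tile each
    chromosome contiguously from 0.

    Returns the window table with ``n_xy``, ``n_zw``, ``n_total`` and
    ``log2_ratio`` = log2((n_xy + c) / (n_zw + c)) columns added.
    """
    stats_df = windows.copy().reset_index(drop=True)
    n_xy = np.zeros(len(stats_df), dtype=int)
    n_zw = np.zeros(len(stats_df), dtype=int)

    labelled = classifications[classifications["label"].isin(["XY", "ZW"])]
    n_unplaced = 0
    # windows tile from 0, so a record's window index is (pos-1) // width
    for chrom, grp in labelled.groupby("chrom", sort=False):
        w = stats_df[stats_df["chrom"] == chrom]
        if w.empty:
            n_unplaced += len(grp)
            logger.warning("%d records on %s not covered by window set",
                           len(grp), chrom)
            continue
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        if (~inside).any():
            n_unplaced += int((~inside).sum())
            logger.warning("%d records on %s fall outside the tiled length",
                           int((~inside).sum()), chrom)
        widx = w.index.to_numpy()[idx[inside]]
        lab = grp["label"].to_numpy()[inside]
        np.add.at(n_xy, widx[lab == "XY"], 1)
        np.add.at(n_zw, widx[lab == "ZW"], 1)

    stats_df["n_xy"] = n_xy
    stats_df["n_zw"] = n_zw
    stats_df["n_total"] = n_xy + n_zw
    c = LOG2_PSEUDOCOUNT
    stats_df["log2_ratio"] = np.log2((n_xy + c) / (n_zw + c))
    stats_df.attrs["n_unplaced"] = n_unplaced
    return stats_df


def top_percent_windows(stats_df: pd.DataFrame, fraction: float = 0.01,
                        anchored_only: bool = True) -> pd.DataFrame:
    """Flag the top-``fraction`` windows by sex-patterned SNP count.

    Exactly ``ceil(fraction * N)`` windows are flagged, where N counts
    anchored windows when ``anchored_only`` (unanchored contigs stay
    unflagged and outside the denominator). Selection is by descending
    ``n_total``; ties break deterministically by (chrom, start) ascending.
    """
    out = stats_df.copy().reset_index(drop=True)
    eligible = out["anchored"].to_numpy() if anchored_only \
        else np.ones(len(out), dtype=bool)
    n_eligible = int(eligible.sum())
    if n_eligible < 1:
        raise ValueError("no anchored windows to rank")
    n_flag = math.ceil(fraction * n_eligible)
    if out.loc[eligible, "n_total"].max() == 0:
        logger.warning("all windows have zero sex-patterned SNPs; "
                       "top-%g%% selection is by coordinate only",
                       100 * fraction)
    ranked = (out[eligible]
              .sort_values(["n_total", "chrom", "start"],
                           ascending=[False, True, True], kind="mergesort"))
    flagged_idx = ranked.index[:n_flag]
    out["top1"] = False
    out.loc[flagged_idx, "top1"] = True
    return out


def _rank_groups(stats_df: pd.DataFrame, value: str):
    groups, labels = [], []
    for chrom, grp in stats_df.groupby("chrom", sort=True):
        vals = grp[value].to_numpy(dtype=float)
        if len(vals) == 0:
            logger.warning("chromosome %s has no windows; excluded", chrom)
            continue
        groups.append(vals)
        labels.append(chrom)
    return groups, labels


def kruskal_wallis_by_chrom(stats_df: pd.DataFrame,
                            value: str = "log2_ratio") -> KruskalResult:
    """Kruskal-Wallis test of ``value`` among chromosomes.

    Tie-corrected H with a chi-square approximation on k-1 df. All-identical
    data (every rank tied) gives H = 0, p = 1 by convention.
    """
    groups, labels = _rank_groups(stats_df, value)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two chromosomes")
    allvals = np.concatenate(groups)
    if np.all(allvals == allvals[0]):
        return KruskalResult(0.0, len(groups) - 1, 1.0)
    H, p = stats.kruskal(*groups)
    return KruskalResult(float(H), len(groups) - 1, float(p))


def dunn_posthoc(stats_df: pd.DataFrame,
                 value: str = "log2_ratio") -> pd.DataFrame:
    """Dunn's post hoc z-tests between chromosomes after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j)) with the pooled,
    tie-corrected rank variance S = N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    Two-sided normal p-values are Benjamini-Hochberg adjusted across all
    pairs. Empty groups are excluded (logged).
    """
    groups, labels = _rank_groups(stats_df, value)
    if len(groups) < 2:
        raise ValueError("Dunn's test needs at least two chromosomes")
    sizes = np.array([len(g) for g in groups])
    allvals = np.concatenate(groups)
    N = len(allvals)
    ranks = stats.rankdata(allvals)
    mean_ranks = []
    offset = 0
    for n in sizes:
        mean_ranks.append(ranks[offset:offset + n].mean())
        offset += n
    _, tie_counts = np.unique(allvals, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    S = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)) if N > 1 else 0.0

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(S * (1.0 / sizes[i] + 1.0 / sizes[j])) if S > 0 else 0.0
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append((labels[i], labels[j], z, p))
    out = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    out["p_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def call_sex_system(stats_df: pd.DataFrame, plurality_floor: float = 0.10,
                    majority: float = 2.0 / 3.0,
                    background_fpr: float = 0.01) -> SexSystemCall:
    """Call the sex chromosome and heterogamety from a flagged window scan.

    A flagged (top-1%) window *supports* a call only when its sex-patterned
    SNP count exceeds a genome-wide background threshold: the
    Poisson(mu_bg) quantile at 1 - background_fpr / N_anchored, where mu_bg
    is the mean count over non-flagged anchored windows. The called
    chromosome is the one holding the plurality of supporting windows; the
    call is ``none`` when no window is supporting or the plurality
    chromosome holds fewer than ``plurality_floor`` of all flagged windows.
    Heterogamety is XY (ZW) when more than ``majority`` of the supporting
    windows on the called chromosome have n_xy > n_zw (n_zw > n_xy), else
    ``mixed``.
    """
    if "top1" not in stats_df.columns:
        raise ValueError("run top_percent_windows first")
    anchored = stats_df[stats_df["anchored"]]
    flagged = anchored[anchored["top1"]]
    background = anchored[~anchored["top1"]]
    if flagged.empty:
        return SexSystemCall(None, "none", 0)
    mu_bg = float(background["n_total"].mean()) if len(background) else 0.0
    q = 1.0 - background_fpr / max(len(anchored), 1)
    threshold = max(1.0, float(stats.poisson.ppf(q, mu_bg)) if mu_bg > 0 else 1.0)
    supporting = flagged[flagged["n_total"] > threshold]
    if supporting.empty:
        return SexSystemCall(None, "none", 0)
    by_chrom = supporting.groupby("chrom").size().sort_values(ascending=False)
    chrom = by_chrom.index[0]
    n_on_chrom = int(by_chrom.iloc[0])
    if n_on_chrom / len(flagged) < plurality_floor:
        return SexSystemCall(None, "none", n_on_chrom)
    on_chrom = supporting[supporting["chrom"] == chrom]
    frac_xy = float((on_chrom["n_xy"] > on_chrom["n_zw"]).mean())
    frac_zw = float((on_chrom["n_zw"] > on_chrom["n_xy"]).mean())
    if frac_xy > majority:
        het = "XY"
    elif frac_zw > majority:
        het = "ZW"
    else:
        het = "mixed"
    intervals = _merge_intervals(list(zip(on_chrom["start"], on_chrom["end"])))
    return SexSystemCall(str(chrom), het, n_on_chrom, intervals)


def _merge_intervals(intervals):
    """Merge touching/overlapping half-open intervals."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged
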