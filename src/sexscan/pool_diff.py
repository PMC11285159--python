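"""Per-site differentiation between male and female DNA pools.

Pool-seq sex scans compare allele frequencies estimated from read counts in a
male pool and a female pool. A sex-limited haplotype (Y or W) that is present
in every heterogametic individual produces the characteristic "sex-patterned"
signature: the linked allele sits near frequency 0.5 in the heterogametic
pool (one of two haplotypes) and near 0 in the homogametic pool. This module
computes per-allele pool frequencies, Wright's two-population F_ST from those
frequencies, and the XY/ZW classification of each allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: column order of the pooled-counts table (male pool then female pool)
MALE_COUNT_COLS = ["A_m", "C_m", "G_m", "T_m"]
FEMALE_COUNT_COLS = ["A_f", "C_f", "G_f", "T_f"]


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds for sex-patterned SNPs.

    An allele is XY-patterned when it is effectively absent in the female
    pool (frequency < ``t_fix``) and at intermediate frequency in the male
    pool (``t_lo`` <= f <= ``t_hi``, closed interval); ZW-patterned is the
    mirror image. ``min_depth`` is the minimum read depth required of *both*
    pools for a site to enter the analysis.
    """

    t_fix: float = 0.1
    t_lo: float = 0.3
    t_hi: float = 0.7
    min_depth: int = 4


def allele_frequencies(counts_male, counts_female):
    """Per-allele pool frequencies at one site.

    Parameters
    ----------
    counts_male, counts_female
        Length-4 sequences of non-negative read counts in A, C, G, T order.

    Returns
    -------
    dict mapping base -> (freq_male, freq_female) for every base with a
    nonzero combined count, or ``None`` when either pool has zero depth
    (the site is skipped with a logged reason, not an exception).
    """
    cm = np.asarray(counts_male, dtype=float)
    cf = np.asarray(counts_female, dtype=float)
    if cm.shape != (4,) or cf.shape != (4,):
        raise ValueError("expected 4 counts (A,C,G,T) per pool")
    if (cm < 0).any() or (cf < 0).any():
        raise ValueError("negative allele count")
    dm, df = cm.sum(), cf.sum()
    if dm == 0 or df == 0:
        logger.info("site skipped: zero depth in %s pool",
                    "male" if dm == 0 else "female")
        return None
    out = {}
    for i, base in enumerate(BASES):
        if cm[i] + cf[i] > 0:
            out[base] = (cm[i] / dm, cf[i] / df)
    return out


def site_fst(freq_male, freq_female):
    """Wright's F_ST between the two pools for one allele.

    With H = 2p(1-p) and the pools equally weighted,
    F_ST = (H_T - mean(H_S)) / H_T, defined as 0 when H_T = 0 (both pools
    fixed for the same state). Accepts scalars or broadcastable arrays and
    returns values in [0, 1].
    """
    p1 = np.asarray(freq_male, dtype=float)
    p2 = np.asarray(freq_female, dtype=float)
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)  # mean of 2p(1-p) over pools
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    return float(fst) if fst.ndim == 0 else fst


def classify_site(freq_male, freq_female, thresholds: Thresholds = Thresholds()):
    """Label one allele as ``"XY"``, ``"ZW"`` or ``"none"``.

    XY: fixed out of the female pool (f_F < t_fix) and polymorphic in the
    male pool (t_lo <= f_M <= t_hi). ZW is the mirror. The two patterns are
    mutually exclusive for a single allele.
    """
    t = thresholds
    if freq_female < t.t_fix and t.t_lo <= freq_male <= t.t_hi:
        return "XY"
    if freq_male < t.t_fix and t.t_lo <= freq_female <= t.t_hi:
        return "ZW"
    return "none"


def classify_sites(counts: pd.DataFrame,
                   thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Classify every allele at every usable site of a pooled-counts table.

    Parameters
    ----------
    counts
        DataFrame with columns ``chrom``, ``pos`` and the eight count
        columns ``A_m..T_m``, ``A_f..T_f``.
    thresholds
        Depth filter and frequency thresholds.

    Returns
    -------
    Long-format DataFrame with one row per (site, allele) for alleles with a
    nonzero combined count at variable sites passing the depth filter:
    columns ``chrom, pos, allele, freq_male, freq_female, fst, label``.
    Sites failing the depth filter or monomorphic across both pools are
    dropped (counts logged).
    """
    cm = counts[MALE_COUNT_COLS].to_numpy(dtype=float)
    cf = counts[FEMALE_COUNT_COLS].to_numpy(dtype=float)
    if (cm < 0).any() or (cf < 0).any():
        raise ValueError("negative allele count in pooled-counts table")
    depth_m = cm.sum(axis=1)
    depth_f = cf.sum(axis=1)
    deep = (depth_m >= thresholds.min_depth) & (depth_f >= thresholds.min_depth)
    variable = ((cm + cf) > 0).sum(axis=1) >= 2
    keep = deep & variable
    n_shallow = int((~deep).sum())
    n_mono = int((deep & ~variable).sum())
    if n_shallow or n_mono:
        logger.info("classify_sites: %d sites below depth %d, %d monomorphic",
                    n_shallow, thresholds.min_depth, n_mono)

    cm, cf = cm[keep], cf[keep]
    depth_m, depth_f = depth_m[keep], depth_f[keep]
    chrom = counts["chrom"].to_numpy()[keep]
    pos = counts["pos"].to_numpy()[keep]

    frames = []
    for i, base in enumerate(BASES):
        present = (cm[:, i] + cf[:, i]) > 0
        if not present.any():
            continue
        fm = cm[present, i] / depth_m[present]
        ff = cf[present, i] / depth_f[present]
        fst = site_fst(fm, ff)
        t = thresholds
        is_xy = (ff < t.t_fix) & (fm >= t.t_lo) & (fm <= t.t_hi)
        is_zw = (fm < t.t_fix) & (ff >= t.t_lo) & (ff <= t.t_hi)
        label = np.where(is_xy, "XY", np.where(is_zw, "ZW", "none"))
        frames.append(pd.DataFrame({
            "chrom": chrom[present],
            "pos": pos[present],
            "allele": base,
            "freq_male": fm,
            "freq_female": ff,
            "fst": np.atleast_1d(fst),
            "label": label,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "allele", "freq_male",
                                     "freq_female", "fst", "label"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "allele"], kind="mergesort",
                          ignore_index=True)
    return out


def per_site_fst(classifications: pd.DataFrame) -> pd.DataFrame:
    """Collapse allele rows to one F_ST per site (maximum across alleles)."""
    return (classifications.groupby(["chrom", "pos"], as_index=False)["fst"]
            .max())
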