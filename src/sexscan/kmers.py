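"""Sex-specific k-mer discovery and cross-population sharing.

Two populations carrying the same sex-limited (Y or W) haplotype by descent
share the k-mers unique to that haplotype; independently evolved systems do
not. This module tabulates canonical k-mers per pool, extracts k-mers
specific to one sex's pool, intersects specific sets between populations,
and places k-mers on a reference by exact match (optionally tolerating one
mismatch) to localise the core region of differentiation.

All k-mers are stored canonically: the lexicographic minimum of the k-mer
and its reverse complement, making every operation strand-agnostic.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

DEFAULT_K = 22
_RC = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_RUN = re.compile(r"[ACGT]+")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _iter_seqs(sequences):
    for item in sequences:
        if isinstance(item, str):
            yield None, item
        else:  # (name, seq) pair or SeqRecord-like
            try:
                name, seq = item
            except (TypeError, ValueError):
                name, seq = item.id, str(item.seq)
            yield name, str(seq)


def count_kmers(sequences, k: int = DEFAULT_K) -> Counter:
    """Tabulate canonical k-mer counts over a set of sequences.

    ``sequences`` is an iterable of strings, (name, sequence) pairs or
    SeqRecords. Windows containing any character outside {A,C,G,T} (e.g. N)
    are skipped; sequences shorter than k contribute nothing (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table: Counter = Counter()
    for name, seq in _iter_seqs(sequences):
        seq = seq.upper()
        if len(seq) < k:
            logger.info("sequence %s shorter than k=%d; skipped",
                        name or "<anonymous>", k)
            continue
        for run in _VALID_RUN.findall(seq):
            for i in range(len(run) - k + 1):
                table[canonical(run[i:i + k])] += 1
    return table


def sex_specific_kmers(focal_table: Counter, other_table: Counter,
                       min_count: int = 2) -> set:
    """K-mers specific to the focal sex's pool.

    Returns k-mers with count >= ``min_count`` in the focal pool and count 0
    in the other pool. The default min_count of 2 guards against singleton
    k-mers created by sequencing error.
    """
    return {kmer for kmer, n in focal_table.items()
            if n >= min_count and other_table.get(kmer, 0) == 0}


def shared_kmers(set_a, set_b) -> set:
    """Exact, symmetric intersection of two k-mer sets (or count tables)."""
    return set(set_a) & set(set_b)


@dataclass
class PlacementResult:
    """Placement of a k-mer set on a reference."""

    per_chrom: Counter = field(default_factory=Counter)  # distinct k-mers/chrom
    positions: dict = field(default_factory=dict)  # kmer -> [(chrom, pos0), ...]
    n_unplaced: int = 0


def _neighbors(kmer: str):
    """All sequences within Hamming distance 1 of ``kmer`` (itself excluded)."""
    for i, base in enumerate(kmer):
        for sub in "ACGT":
            if sub != base:
                yield kmer[:i] + sub + kmer[i + 1:]


def build_reference_index(reference, k: int = DEFAULT_K) -> dict:
    """Index a reference (dict name -> sequence, or (name, seq) pairs) by
    canonical k-mer -> list of (chrom, 0-based position)."""
    index: dict = {}
    items = reference.items() if hasattr(reference, "items") else reference
    for chrom, seq in items:
        seq = str(seq).upper()
        offset = 0
        for match in _VALID_RUN.finditer(seq):
            run = match.group(0)
            for i in range(len(run) - k + 1):
                index.setdefault(canonical(run[i:i + k]),
                                 []).append((chrom, match.start() + i))
        del offset
    return index


def place_kmers(kmer_set, reference, k: int | None = None,
                max_mismatch: int = 0, index: dict | None = None
                ) -> PlacementResult:
    """Place k-mers on a reference by exact (or 1-mismatch) matching.

    Each k-mer is reported at every matching locus; ``per_chrom`` counts
    distinct k-mers with at least one match on that chromosome, and k-mers
    with no match anywhere are tallied as unplaced. ``max_mismatch`` of 1
    enumerates all single-substitution neighbours of each query.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    kmer_set = set(kmer_set)
    if index is None:
        if k is None:
            k = len(next(iter(kmer_set))) if kmer_set else DEFAULT_K
        index = build_reference_index(reference, k=k)
    result = PlacementResult()
    for kmer in sorted(kmer_set):
        queries = [canonical(kmer)]
        if max_mismatch == 1:
            queries += [canonical(n) for n in _neighbors(kmer)]
        hits = []
        for q in queries:
            hits.extend(index.get(q, ()))
        if not hits:
            result.n_unplaced += 1
            continue
        result.positions[kmer] = sorted(set(hits))
        for chrom in {c for c, _ in hits}:
            result.per_chrom[chrom] += 1
    return result
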