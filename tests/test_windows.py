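"""Window tiling, top-percent selection, rank tests and the sex-system call."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from sexscan import windows
from sexscan.windows import (call_sex_system, count_in_windows, dunn_posthoc,
                             kruskal_wallis_by_chrom, make_windows,
                             top_percent_windows)


def tiling_oracle(size, width):
    """Brute-force enumeration of tile boundaries."""
    out = []
    start = 0
    while start < size:
        out.append((start, min(start + width, size)))
        start += width
    return out


def kruskal_oracle(groups):
    """Tie-corrected H computed from first principles on small inputs."""
    allvals = np.concatenate(groups)
    N = len(allvals)
    order = np.argsort(allvals, kind="mergesort")
    ranks = np.empty(N)
    i = 0
    sorted_vals = allvals[order]
    while i < N:
        j = i
        while j < N and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # average rank, 1-based
        i = j
    offset, H = 0, 0.0
    for g in groups:
        r = ranks[offset:offset + len(g)]
        H += len(g) * (r.mean() - (N + 1) / 2) ** 2
        offset += len(g)
    H *= 12 / (N * (N + 1))
    _, t = np.unique(allvals, return_counts=True)
    correction = 1 - np.sum(t ** 3 - t) / (N ** 3 - N)
    return H / correction if correction > 0 else 0.0


def dunn_oracle(groups):
    """Pairwise Dunn z from the textbook formula, independent code path."""
    allvals = np.concatenate(groups)
    N = len(allvals)
    ranks = sps.rankdata(allvals)
    mean_ranks, sizes, offset = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[offset:offset + len(g)].mean())
        sizes.append(len(g))
        offset += len(g)
    _, t = np.unique(allvals, return_counts=True)
    S = N * (N + 1) / 12 - np.sum(t ** 3 - t) / (12 * (N - 1))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(S * (1 / sizes[i] + 1 / sizes[j]))
            out[(i, j)] = (mean_ranks[i] - mean_ranks[j]) / se
    return out


def _stats_frame(counts_by_chrom):
    rows = []
    for chrom, vals in counts_by_chrom.items():
        for i, v in enumerate(vals):
            rows.append((chrom, i * 100_000, (i + 1) * 100_000, True, v))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "anchored",
                                     "log2_ratio"])
    return df


class TestMakeWindows:
    def test_arithmetic(self):
        w = make_windows({"chr1": 250_000})
        assert len(w) == 3
        assert w.iloc[-1]["end"] - w.iloc[-1]["start"] == 50_000

    def test_anchored_genome_window_count(self):
        w = make_windows({"genome": 780_000_000})
        assert len(w) == 7_800

    @given(st.lists(st.integers(1, 10**6), min_size=1, max_size=5),
           st.integers(500, 10**5))
    def test_matches_bruteforce_tiling(self, sizes, width):
        chrom_sizes = {f"c{i}": s for i, s in enumerate(sizes)}
        w = make_windows(chrom_sizes, width=width)
        for chrom, size in chrom_sizes.items():
            sub = w[w["chrom"] == chrom]
            assert list(zip(sub["start"], sub["end"])) == \
                tiling_oracle(size, width)
            assert len(sub) == math.ceil(size / width)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            make_windows({})


class TestCountInWindows:
    def _cls(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "label"])

    def test_single_window_counts(self):
        w = make_windows({"chr1": 50_000})
        cls = self._cls([("chr1", p, "XY") for p in range(1, 6)])
        st_df = count_in_windows(cls, w)
        assert st_df["n_xy"].tolist() == [5]

    def test_boundary_position_coordinate_convention(self):
        """1-based site 100,000 is the last base of window [0, 100000);
        site 100,001 opens the second window."""
        w = make_windows({"chr1": 200_000})
        cls = self._cls([("chr1", 100_000, "XY"), ("chr1", 100_001, "ZW")])
        st_df = count_in_windows(cls, w)
        assert st_df["n_xy"].tolist() == [1, 0]
        assert st_df["n_zw"].tolist() == [0, 1]

    def test_empty_input_gives_zero_windows(self):
        w = make_windows({"chr1": 300_000})
        st_df = count_in_windows(self._cls([]), w)
        assert (st_df["n_total"] == 0).all()
        assert np.allclose(st_df["log2_ratio"], 0.0)

    def test_conservation_and_unplaced(self, rng):
        w = make_windows({"chr1": 1_000_000, "chr2": 500_000})
        rows = [("chr1", int(p), "XY") for p in rng.integers(1, 10**6, 200)]
        rows += [("chr2", int(p), "ZW") for p in rng.integers(1, 5 * 10**5, 100)]
        rows += [("chrUn", 5, "XY")]
        st_df = count_in_windows(self._cls(rows), w)
        assert st_df["n_xy"].sum() == 200
        assert st_df["n_zw"].sum() == 100
        assert st_df.attrs["n_unplaced"] == 1


class TestTopPercent:
    def test_78_of_7800(self):
        st_df = count_in_windows(pd.DataFrame(columns=["chrom", "pos", "label"]),
                                 make_windows({"genome": 780_000_000}))
        flagged = top_percent_windows(st_df)
        assert int(flagged["top1"].sum()) == 78

    @given(st.integers(1, 500))
    def test_flag_count_is_ceil(self, n):
        df = pd.DataFrame({"chrom": "c", "start": np.arange(n) * 100,
                           "end": (np.arange(n) + 1) * 100, "anchored": True,
                           "n_total": 0, "n_xy": 0, "n_zw": 0})
        out = top_percent_windows(df)
        assert int(out["top1"].sum()) == math.ceil(0.01 * n)

    def test_matches_sort_oracle_and_tiebreak(self, rng):
        n = 400
        df = pd.DataFrame({"chrom": rng.choice(["a", "b"], n),
                           "start": np.tile(np.arange(200) * 100, 2),
                           "end": 0, "anchored": True,
                           "n_total": rng.integers(0, 5, n)})
        df["end"] = df["start"] + 100
        out = top_percent_windows(df, fraction=0.05)
        expect = set(df.sort_values(["n_total", "chrom", "start"],
                                    ascending=[False, True, True],
                                    kind="mergesort").index[:20])
        assert set(out.index[out["top1"]]) == expect

    def test_unanchored_outside_denominator(self):
        df = pd.DataFrame({"chrom": ["a"] * 100 + ["contig"] * 100,
                           "start": list(range(100)) * 2, "end": 0,
                           "anchored": [True] * 100 + [False] * 100,
                           "n_total": [0] * 100 + [99] * 100})
        out = top_percent_windows(df)
        assert int(out["top1"].sum()) == 1
        assert out[out["top1"]]["chrom"].tolist() == ["a"]


class TestRankStatistics:
    def test_all_identical_gives_zero_H(self):
        df = _stats_frame({"a": [1.0] * 5, "b": [1.0] * 5})
        res = kruskal_wallis_by_chrom(df)
        assert res.H == 0.0 and res.pvalue == 1.0

    def test_two_group_exact_rank_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        df = _stats_frame({"a": groups[0], "b": groups[1]})
        res = kruskal_wallis_by_chrom(df)
        assert res.H == pytest.approx(kruskal_oracle(groups))
        assert res.df == 1

    def test_small_instances_match_bruteforce(self, rng):
        """H and Dunn z agree with first-principles implementations on
        random instances with at most 12 observations."""
        for _ in range(25):
            k = rng.integers(2, 4)
            sizes = rng.integers(2, 5, size=k)
            while sizes.sum() > 12:
                sizes[rng.integers(k)] = 2
            groups = [rng.integers(0, 6, size=n).astype(float) for n in sizes]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            df = _stats_frame({f"g{i}": g for i, g in enumerate(groups)})
            res = kruskal_wallis_by_chrom(df)
            assert res.H == pytest.approx(kruskal_oracle(groups))
            dunn = dunn_posthoc(df)
            oracle = dunn_oracle(groups)
            for (i, j), z in oracle.items():
                row = dunn[(dunn["group1"] == f"g{i}")
                           & (dunn["group2"] == f"g{j}")]
                assert row["z"].iloc[0] == pytest.approx(z)

    def test_single_group_errors(self):
        df = _stats_frame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            kruskal_wallis_by_chrom(df)

    def test_identical_groups_z_zero_p_one(self):
        df = _stats_frame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        dunn = dunn_posthoc(df)
        assert dunn["z"].iloc[0] == pytest.approx(0.0)
        assert dunn["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_bh_stepup_arithmetic(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.9], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.9])

    def test_bh_adjusted_at_least_raw(self, rng):
        df = _stats_frame({c: rng.normal(size=8) for c in "abcd"})
        dunn = dunn_posthoc(df)
        assert (dunn["p_bh"] >= dunn["p_raw"] - 1e-15).all()
        # monotone in raw-p order
        s = dunn.sort_values("p_raw")
        assert (np.diff(s["p_bh"]) >= -1e-15).all()


class TestCallSexSystem:
    def _scan(self, seed, heterogamety):
        from sexscan import pool_diff, simulate
        spec = None
        if heterogamety is not None:
            spec = simulate.default_sex_system(heterogamety=heterogamety)
        counts, _ = simulate.simulate_pooled_counts(sex_systems=spec,
                                                    seed=seed)
        cls = pool_diff.classify_sites(counts)
        w = make_windows({c: 5_000_000 for c in ("chr1", "chr2", "chr3")})
        return top_percent_windows(count_in_windows(cls, w))

    def test_clear_xy_system_called(self):
        call = call_sex_system(self._scan(5, "XY"))
        assert (call.chrom, call.heterogamety) == ("chr2", "XY")
        assert call.intervals and all(2_000_000 <= s and e <= 3_000_000
                                      for s, e in call.intervals)

    def test_zw_mirror(self):
        call = call_sex_system(self._scan(6, "ZW"))
        assert (call.chrom, call.heterogamety) == ("chr2", "ZW")

    def test_null_scan_called_none(self):
        call = call_sex_system(self._scan(7, None))
        assert call.heterogamety == "none"

    def test_split_below_plurality_floor_is_none(self):
        df = pd.DataFrame({
            "chrom": [f"c{i}" for i in range(20)],
            "start": 0, "end": 100_000, "anchored": True,
            "n_xy": 50, "n_zw": 0, "n_total": 50,
            "top1": True})
        # each chromosome holds 5% of flagged windows, below the 10% floor
        call = call_sex_system(df, background_fpr=1e-9)
        assert call.heterogamety == "none"
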