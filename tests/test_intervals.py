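"""Interval arithmetic, shuffle permutation null, and signal aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dmlkit.genome import GenomeModel
from dmlkit.intervals import (
    aggregate_signal,
    compare_anchor_signal,
    merge_peaks,
    permutation_overlap_test,
    shuffle_intervals,
    window_overlap_count,
)


def peaks(rows, chrom="chr1"):
    return pd.DataFrame([(chrom, s, e) for s, e in rows],
                        columns=["chrom", "start", "end"])


def toy_genome(lengths):
    names = list(lengths)
    return GenomeModel(names, dict(lengths),
                       {c: np.array([], dtype=int) for c in names})


def brute_force_merge(intervals):
    """Sweep-line union with book-ended coalescing."""
    out = []
    for chrom in sorted(set(intervals["chrom"])):
        ivs = sorted(intervals[intervals["chrom"] == chrom][["start", "end"]]
                     .itertuples(index=False, name=None))
        cur = list(ivs[0])
        for s, e in ivs[1:]:
            if s <= cur[1]:
                cur[1] = max(cur[1], e)
            else:
                out.append((chrom, *cur))
                cur = [s, e]
        out.append((chrom, *cur))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


class TestMergePeaks:
    def test_overlap_coalesced(self):
        out = merge_peaks(peaks([(10, 20)]), peaks([(15, 30)]))
        assert out.values.tolist() == [["chr1", 10, 30]]

    def test_book_ended_coalesced(self):
        out = merge_peaks(peaks([(10, 20)]), peaks([(20, 30)]))
        assert out.values.tolist() == [["chr1", 10, 30]]

    def test_invalid_interval_rejected_with_coordinates(self):
        with pytest.raises(ValueError, match="chr1:30-20"):
            merge_peaks(peaks([(30, 20)]))

    def test_idempotent_and_commutative_vs_sweep_line(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 10_000, 1000)
        a = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 1000),
                          "start": starts, "end": starts + rng.integers(1, 300, 1000)})
        b = a.iloc[500:]
        a = a.iloc[:500]
        m1 = merge_peaks(a, b).reset_index(drop=True)
        m2 = merge_peaks(b, a).reset_index(drop=True)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(m1, merge_peaks(m1).reset_index(drop=True))
        expected = brute_force_merge(pd.concat([a, b])).sort_values(
            ["chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(m1.sort_values(["chrom", "start"]).reset_index(drop=True),
                                      expected)


class TestWindowOverlap:
    def test_half_open_boundary_arithmetic(self):
        dml = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})  # 0-based point 99
        pk = peaks([(150, 200)])
        assert window_overlap_count(dml, pk, 50)[0] == 0  # extended [100,250) misses 99
        assert window_overlap_count(dml, pk, 51)[0] == 1

    def test_zero_window_inside_peak(self):
        dml = pd.DataFrame({"chrom": ["chr1"], "pos": [160]})
        assert window_overlap_count(dml, peaks([(150, 200)]), 0)[0] == 1

    def test_monotone_in_window(self):
        rng = np.random.default_rng(7)
        dml = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 100_000, 500)})
        starts = rng.integers(0, 100_000, 100)
        pk = peaks(list(zip(starts, starts + rng.integers(50, 400, 100))))
        counts = [window_overlap_count(dml, pk, w)[0] for w in (0, 100, 500, 10_000)]
        assert counts == sorted(counts)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(12)
        dml = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 2000),
                            "pos": rng.integers(1, 500_000, 2000)})
        starts = rng.integers(0, 500_000, 300)
        pk = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 300),
                           "start": starts, "end": starts + rng.integers(50, 2000, 300)})
        for w in (0, 500, 10_000):
            got = window_overlap_count(dml, pk, w)[0]
            expected = 0
            for _, d in dml.iterrows():
                pt = d["pos"] - 1
                sub = pk[pk["chrom"] == d["chrom"]]
                if ((sub["start"] - w <= pt) & (pt < sub["end"] + w)).any():
                    expected += 1
            assert got == expected


class TestShuffle:
    def test_conserves_length_multiset_and_determinism(self):
        g = toy_genome({"chr1": 10_000, "chr2": 5_000})
        pk = peaks([(0, 100), (500, 900), (2000, 2050)])
        s1 = shuffle_intervals(pk, g, 3)
        s2 = shuffle_intervals(pk, g, 3)
        pd.testing.assert_frame_equal(s1, s2)
        assert sorted(s1["end"] - s1["start"]) == sorted(pk["end"] - pk["start"])
        for _, row in s1.iterrows():
            assert 0 <= row["start"] < row["end"] <= g.chrom_lengths[row["chrom"]]

    def test_start_uniform_on_feasible_range(self):
        g = toy_genome({"chr1": 1000})
        pk = peaks([(0, 100)])
        rng = np.random.default_rng(0)
        starts = [shuffle_intervals(pk, g, rng)["start"].iloc[0] for _ in range(10_000)]
        expected_mean = (1000 - 100) / 2
        se = (1000 - 100) / np.sqrt(12 * 10_000)
        assert abs(np.mean(starts) - expected_mean) < 3 * se

    def test_peak_longer_than_every_chromosome_rejected(self):
        g = toy_genome({"chr1": 1000})
        with pytest.raises(ValueError):
            shuffle_intervals(peaks([(0, 2000)]), g, 1)


class TestPermutationTest:
    def test_anti_enriched_placement_gives_large_p(self):
        # peak [0,900) misses the point at 0-based 989; a shuffled 900 bp peak
        # covers it for starts 90..100, i.e. with exact probability 11/101
        g = toy_genome({"chr1": 1000})
        dml = pd.DataFrame({"chrom": ["chr1"], "pos": [990]})
        pk = peaks([(0, 900)])
        res = permutation_overlap_test(dml, pk, g, 0, n_perm=400, seed=1)[0]
        assert res.observed == 0
        exact = 11 / 101
        se = np.sqrt(exact * (1 - exact) / 400)
        assert abs(res.empirical_p - exact) <= 3 * se
        assert res.empirical_p > 0.05  # anti-enriched: nowhere near significant

    def test_matches_exhaustive_enumeration_on_toy_genome(self):
        # one 10 bp peak on a 100 bp chromosome, one DML at position 50 (point 49),
        # w=0: exact P(cover) = 10/91 placements
        g = toy_genome({"chr1": 100})
        dml = pd.DataFrame({"chrom": ["chr1"], "pos": [50]})
        pk = peaks([(90, 100)])
        res = permutation_overlap_test(dml, pk, g, 0, n_perm=4000, seed=5)[0]
        exact = 10 / 91
        se = np.sqrt(exact * (1 - exact) / 4000)
        # observed overlap is 0, so empirical p = fraction of shuffles covering the point
        assert res.observed == 0
        assert abs(res.empirical_p - exact) < 3 * se

    def test_strong_enrichment_reports_below_resolution(self, genome):
        from dmlkit.simulate import PeakEnrichmentParams, simulate_peaks_and_signal
        truth = pd.DataFrame({"chrom": "chr1", "pos": genome.cpg_positions["chr1"][:80],
                              "true_delta": -0.5, "direction": "hypo"})
        for seed in (1, 2, 3):
            _, eff, _, _ = simulate_peaks_and_signal(
                genome, truth, PeakEnrichmentParams(enrichment_fraction=0.9), seed=seed)
            res = permutation_overlap_test(truth, eff, genome, 500, n_perm=200, seed=seed)[0]
            assert res.empirical_p == 0.0
            assert res.reported_p == "<0.005"

    def test_windows_vector_in_one_call(self):
        g = toy_genome({"chr1": 10_000})
        rng = np.random.default_rng(2)
        dml = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 10_000, 50)})
        starts = rng.integers(0, 9_900, 20)
        pk = peaks(list(zip(starts, starts + 50)))
        res = permutation_overlap_test(dml, pk, g, [0, 500, 1000], n_perm=50, seed=9)
        assert [r.window for r in res] == [0, 500, 1000]
        obs = [r.observed for r in res]
        assert obs == sorted(obs)


class TestAggregateSignal:
    def _track(self, rows, chrom="chr1"):
        return pd.DataFrame([(chrom, s, e, v) for s, e, v in rows],
                            columns=["chrom", "start", "end", "value"])

    def test_constant_track(self):
        track = self._track([(0, 100_000, 5.0)])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000]})
        mat, mean, trunc = aggregate_signal(track, anchors, flank=2000, n_bins=40)
        np.testing.assert_allclose(mat, 5.0)
        assert not trunc.any()

    def test_zero_track(self):
        track = self._track([(0, 100, 0.0)])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000]})
        mat, _, _ = aggregate_signal(track, anchors, flank=2000, n_bins=40)
        np.testing.assert_allclose(mat, 0.0)

    def test_truncated_window_flagged_and_zero_padded(self):
        track = self._track([(0, 10_000, 3.0)])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        mat, _, trunc = aggregate_signal(track, anchors, flank=2000, n_bins=4)
        assert trunc[0]
        assert mat[0, 0] < 3.0  # left part of the window is off-chromosome

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(21)
        edges = np.sort(rng.choice(np.arange(1, 20_000), 60, replace=False))
        rows = []
        for s, e in zip(edges[:-1], edges[1:]):
            if rng.random() < 0.6:  # leave gaps
                rows.append((int(s), int(e), float(rng.uniform(0, 10))))
        track = self._track(rows)
        anchors = pd.DataFrame({"chrom": "chr1",
                                "pos": rng.integers(3000, 17_000, 50)})
        flank, n_bins = 2000, 40
        mat, mean, _ = aggregate_signal(track, anchors, flank=flank, n_bins=n_bins)
        base = np.zeros(25_000)
        for s, e, v in rows:
            base[s:e] = v
        binw = 2 * flank // n_bins
        for i, pos in enumerate(anchors["pos"]):
            win = base[pos - 1 - flank: pos - 1 + flank]
            expected = win.reshape(n_bins, binw).mean(axis=1)
            np.testing.assert_allclose(mat[i], expected, atol=1e-9)
        np.testing.assert_allclose(mean, mat.mean(axis=0))


class TestCompareAnchorSignal:
    def test_identical_vectors_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = compare_anchor_signal(a, a)
        assert out["t"] == 0 and out["pvalue"] == pytest.approx(1.0)

    def test_separated_means_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.01, 10)
        b = 1 + rng.normal(0, 0.01, 10)
        assert compare_anchor_signal(a, b)["pvalue"] < 1e-6

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.3, 1, 12)
        out = compare_anchor_signal(a, b)
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert out["t"] == pytest.approx(t)
        assert out["pvalue"] == pytest.approx(2 * stats.t.sf(abs(t), len(a) + len(b) - 2))

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            compare_anchor_signal([1.0], [2.0])


def test_null_placement_permutation_p_uniform(genome):
    """Under unenriched peak placement the empirical p is ~uniform: over 200
    simulated datasets the fraction with p <= 0.05 is within 3 SE of 0.05."""
    from dmlkit.simulate import PeakEnrichmentParams, simulate_peaks_and_signal
    rng = np.random.default_rng(77)
    n_data, n_perm = 200, 99
    hits = 0
    pos_all = genome.cpg_positions["chr1"]
    for i in range(n_data):
        dml = pd.DataFrame({"chrom": "chr1",
                            "pos": rng.choice(pos_all, 40, replace=False)})
        _, eff, _, _ = simulate_peaks_and_signal(
            genome, pd.DataFrame(columns=["chrom", "pos", "true_delta", "direction"]),
            PeakEnrichmentParams(enrichment_fraction=0.0, n_background=25), seed=int(i))
        res = permutation_overlap_test(dml, eff, genome, 500, n_perm=n_perm, seed=int(i))[0]
        if res.empirical_p <= 0.05:
            hits += 1
    # discrete null: P(p <= 0.05) = (floor(0.05*n_perm)+1)/(n_perm+1)
    target = (int(0.05 * n_perm) + 1) / (n_perm + 1)
    se = np.sqrt(target * (1 - target) / n_data)
    assert abs(hits / n_data - target) <= 3 * se
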