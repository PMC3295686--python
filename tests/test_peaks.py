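"""Peak-calling core: window counts, null fit, empirical FDR, merge, Wilcoxon."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mbdscan.io import ReadAlignment
from mbdscan.peaks import (CandidateWindow, MBDScan, compute_fdr_table,
                           count_windows, fit_null, merge_candidates,
                           rank_sum_left_p, refine_peaks, scan_candidates)
from tests.conftest import make_reads


def brute_force_fdr_table(counts, null, form="tail"):
    """Independent per-count loop over tail (or point) fractions."""
    counts = np.asarray(counts)
    n = len(counts)
    table = {}
    for c in np.unique(counts):
        if form == "tail":
            expected = float(null.sf(int(c)))
            observed = float((counts >= c).sum()) / n
        else:
            expected = float(null.pmf(int(c)))
            observed = float((counts == c).sum()) / n
        table[int(c)] = min(max(expected / observed, 0.0), 1.0)
    return table


def enumerate_rank_sum_p(forward, reverse):
    """Full permutation enumeration of P(W <= W_obs), midranks for ties."""
    pooled = np.concatenate([forward, reverse]).astype(float)
    ranks = stats.rankdata(pooled)
    n = len(forward)
    w_obs = ranks[:n].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(idx)].sum() <= w_obs + 1e-9:
            hits += 1
    return hits / total


class TestCountWindows:
    def test_no_reads_all_zero(self, chrom_sizes):
        track = count_windows([], chrom_sizes, 300, 100)
        assert track.all_counts().sum() == 0
        assert track.n_windows == sum(
            int(np.ceil(l / 100)) for l in chrom_sizes.values())

    def test_single_plus_read_counted_by_five_prime(self):
        track = count_windows([ReadAlignment("chr1", 100, 250, "+")],
                              {"chr1": 1200}, 300, 300)
        starts, counts = track.windows["chr1"]
        assert counts.tolist() == [1, 0, 0, 0]

    def test_minus_read_uses_end_minus_one(self):
        # 5' of a '-' read at [100, 250) is 249 -> window [0, 300) still
        # but [290, 450) has 5' 449 -> second window
        track = count_windows([ReadAlignment("chr1", 290, 450, "-")],
                              {"chr1": 1200}, 300, 300)
        _, counts = track.windows["chr1"]
        assert counts.tolist() == [0, 1, 0, 0]

    def test_sliding_windows_count_every_containing_window(self):
        track = count_windows([ReadAlignment("chr1", 250, 400, "+")],
                              {"chr1": 1200}, 300, 100)
        starts, counts = track.windows["chr1"]
        # 5' = 250 lies in windows starting at 0, 100, 200
        expected = [1 if s <= 250 < s + 300 else 0 for s in starts]
        assert counts.tolist() == expected

    def test_conservation_on_tiling_partition(self):
        rng = np.random.default_rng(0)
        reads = make_reads(rng.integers(0, 1_000_000, size=1000))
        track = count_windows(reads, {"chr1": 1_000_000}, 300, 300)
        assert track.all_counts().sum() == 1000

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError, match="chrMystery"):
            count_windows([ReadAlignment("chrMystery", 0, 100, "+")],
                          {"chr1": 1000}, 300, 100)

    def test_last_partial_window_kept(self):
        track = count_windows([ReadAlignment("chr1", 950, 1000, "+")],
                              {"chr1": 1000}, 300, 300)
        starts, counts = track.windows["chr1"]
        assert starts.tolist() == [0, 300, 600, 900]
        assert counts.tolist() == [0, 0, 0, 1]


class TestFitNull:
    def test_constant_counts_poisson_fallback(self):
        reads = make_reads(range(0, 9000, 3))  # exactly 100 reads per window
        track = count_windows(reads, {"chr1": 9000}, 300, 300)
        null = fit_null(track, 1.0)
        assert null.is_poisson
        assert null.mu == pytest.approx(100.0)

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(42)
        mu, k = 3.0, 2.0
        counts = rng.negative_binomial(k, k / (k + mu), size=100_000)
        reads = []
        pos = 0
        for c in counts:  # c reads with 5' in each consecutive 300 bp window
            reads.extend(make_reads([pos + i % 300 for i in range(c)]))
            pos += 300
        track = count_windows(reads, {"chr1": pos}, 300, 300)
        null = fit_null(track, 1.0)
        assert null.mu == pytest.approx(mu, rel=0.02)
        assert null.k == pytest.approx(k, rel=0.10)

    def test_quantile_cutoff_filters_fit_windows(self):
        # counts {0,0,1,1,5,9}: median cutoff 1, fit uses the four low windows
        positions = [600, 900] + list(range(1200, 1205)) + list(range(1500, 1509))
        reads = make_reads(positions)
        track = count_windows(reads, {"chr1": 1800}, 300, 300)
        assert sorted(track.all_counts().tolist()) == [0, 0, 1, 1, 5, 9]
        null = fit_null(track, 0.5)
        assert null.low_coverage_cutoff == pytest.approx(1.0)
        assert null.n_windows_used == 4
        assert null.mu == pytest.approx(0.5)

    def test_all_zero_counts_degenerate(self):
        track = count_windows([], {"chr1": 3000}, 300, 300)
        null = fit_null(track, 0.9)
        assert null.degenerate
        assert float(null.sf(1)) == 0.0  # any window with a read is called


class TestFdrTable:
    @pytest.mark.parametrize("form", ["tail", "per_count"])
    def test_matches_brute_force_oracle(self, form):
        rng = np.random.default_rng(1)
        reads = make_reads(rng.integers(0, 300_000, size=3000))
        track = count_windows(reads, {"chr1": 300_000}, 300, 300)
        null = fit_null(track, 0.9)
        table = compute_fdr_table(track, null, form=form)
        oracle = brute_force_fdr_table(track.all_counts(), null, form=form)
        for c, raw in zip(table.counts, table.raw):
            assert raw == pytest.approx(oracle[int(c)], abs=1e-12)

    def test_direct_ratio(self):
        # one window at count 10 among 100 windows, null tail 0.001 -> FDR 0.1
        class FakeNull:
            def sf(self, c):
                return np.where(np.asarray(c) >= 10, 0.001, 1.0)

        reads = make_reads([0] * 10)
        track = count_windows(reads, {"chr1": 30_000}, 300, 300)
        table = compute_fdr_table(track, FakeNull())
        assert table.counts.tolist() == [0, 10]
        assert table.raw[-1] == pytest.approx(0.001 / 0.01)

    def test_null_equals_observed_gives_fdr_near_one(self):
        rng = np.random.default_rng(3)
        mu, k = 3.0, 2.0
        counts = rng.negative_binomial(k, k / (k + mu), size=50_000)
        reads = []
        for i, c in enumerate(counts):
            reads.extend(make_reads([i * 300] * c))
        track = count_windows(reads, {"chr1": 300 * len(counts)}, 300, 300)
        null = fit_null(track, 1.0)
        table = compute_fdr_table(track, null)
        # bulk of the distribution: FDR ~ 1 up to modest sampling noise
        bulk = table.counts <= np.quantile(counts, 0.99)
        assert np.all(table.raw[bulk] > 0.8)

    def test_monotonization_never_increases_and_is_non_increasing(self):
        rng = np.random.default_rng(4)
        reads = make_reads(rng.integers(0, 60_000, size=2000))
        track = count_windows(reads, {"chr1": 60_000}, 300, 100)
        table = compute_fdr_table(track, fit_null(track, 0.9))
        assert np.all(table.fdr <= table.raw + 1e-15)
        assert np.all(np.diff(table.fdr) <= 1e-15)


class TestScanAndMerge:
    def _spiked_track(self):
        rng = np.random.default_rng(5)
        background = make_reads(rng.integers(0, 300_000, size=3000))
        spike = make_reads([150_050] * 50)
        track = count_windows(background + spike, {"chr1": 300_000}, 300, 300)
        return track, background + spike

    def test_spiked_window_is_the_only_call(self):
        track, _ = self._spiked_track()
        null = fit_null(track, 0.9)
        table = compute_fdr_table(track, null)
        hits = scan_candidates(track, table, 0.01)
        assert len(hits) == 1
        assert hits[0].start == 150_000
        assert hits[0].fdr <= 0.01

    def test_permissive_limit_returns_all_nonzero_windows(self):
        track, _ = self._spiked_track()
        table = compute_fdr_table(track, fit_null(track, 0.9))
        hits = scan_candidates(track, table, 1.0)
        assert len(hits) == int((track.all_counts() >= 1).sum())

    def test_threshold_monotonicity(self):
        track, _ = self._spiked_track()
        table = compute_fdr_table(track, fit_null(track, 0.9))
        calls = {a: {(w.chrom, w.start) for w in scan_candidates(track, table, a)}
                 for a in (0.001, 0.01, 0.1, 1.0)}
        assert calls[0.001] <= calls[0.01] <= calls[0.1] <= calls[1.0]

    def test_merge_overlap_union(self):
        ws = [CandidateWindow("chr1", 0, 300, 5, 0.01),
              CandidateWindow("chr1", 200, 500, 6, 0.002)]
        (peak,) = merge_candidates(ws)
        assert (peak.start, peak.end) == (0, 500)
        assert peak.min_window_fdr == 0.002

    def test_merge_disjoint_stays_separate(self):
        ws = [CandidateWindow("chr1", 0, 300, 5, 0.01),
              CandidateWindow("chr1", 600, 900, 6, 0.002)]
        assert len(merge_candidates(ws)) == 2

    def test_bookended_only_merge_when_enabled(self):
        ws = [CandidateWindow("chr1", 0, 300, 5, 0.01),
              CandidateWindow("chr1", 300, 600, 6, 0.002)]
        assert len(merge_candidates(ws)) == 2
        assert len(merge_candidates(ws, merge_bookended=True)) == 1

    def test_merge_matches_union_find_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            starts = np.sort(rng.choice(np.arange(0, 5000, 100), size=12,
                                        replace=False))
            ws = [CandidateWindow("chr1", int(s), int(s) + 300, 1, 0.5)
                  for s in starts]
            spans = [(p.start, p.end) for p in merge_candidates(ws)]
            # oracle: union-find over the pairwise overlap graph
            parent = list(range(len(ws)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i, j in itertools.combinations(range(len(ws)), 2):
                if min(ws[i].end, ws[j].end) > max(ws[i].start, ws[j].start):
                    parent[find(i)] = find(j)
            groups = {}
            for i in range(len(ws)):
                groups.setdefault(find(i), []).append(ws[i])
            oracle = sorted((min(w.start for w in g), max(w.end for w in g))
                            for g in groups.values())
            assert sorted(spans) == oracle

    def test_merged_peaks_pairwise_disjoint(self):
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 10_000, size=50)
        ws = [CandidateWindow("chr1", int(s), int(s) + 300, 1, 0.5)
              for s in starts]
        peaks = sorted(merge_candidates(ws), key=lambda p: p.start)
        assert all(a.end <= b.start for a, b in zip(peaks, peaks[1:]))

    def test_peak_read_count_recounted_over_span(self):
        reads = make_reads([10, 20, 250, 310, 2000])
        ws = [CandidateWindow("chr1", 0, 300, 3, 0.01),
              CandidateWindow("chr1", 200, 500, 2, 0.01)]
        (p1, p2) = merge_candidates(ws + [CandidateWindow("chr1", 1900, 2200, 1, 0.01)],
                                    reads, {"chr1": 3000})
        assert p1.read_count == 4   # 5' in [0, 500)
        assert p2.read_count == 1


class TestRankSumRefinement:
    def test_textbook_separated_case(self):
        p = rank_sum_left_p(np.array([10, 20, 30]), np.array([40, 50, 60]))
        assert p == pytest.approx(1 / 20)

    def test_symmetric_case_not_significant(self):
        p = rank_sum_left_p(np.array([1, 2, 3]), np.array([1, 2, 3]))
        assert p >= 0.5

    def test_reversed_orientation_is_large(self):
        p = rank_sum_left_p(np.array([40, 50, 60]), np.array([10, 20, 30]))
        assert p == pytest.approx(1.0)

    def test_matches_full_enumeration_random_positions(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n, m = rng.integers(2, 9, size=2)
            fwd = rng.integers(0, 30, size=n)
            rev = rng.integers(0, 30, size=m)
            assert rank_sum_left_p(fwd, rev) == pytest.approx(
                enumerate_rank_sum_p(fwd, rev), abs=1e-12)

    def test_normal_approximation_tracks_exact_at_boundary(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            fwd = rng.normal(0, 5, size=10).round()
            rev = rng.normal(3, 5, size=10).round()
            exact = rank_sum_left_p(fwd, rev)                 # n+m = 20: exact
            approx_stat = stats.mannwhitneyu(fwd, rev, alternative="less",
                                             method="asymptotic")
            assert exact == pytest.approx(approx_stat.pvalue, abs=0.02)

    def test_too_few_reads_on_a_strand_gives_p_one(self):
        assert rank_sum_left_p(np.array([1]), np.array([5, 6, 7])) == 1.0

    def test_refine_annotates_without_dropping_by_default(self, chrom_sizes):
        fwd = make_reads([1000, 1050, 1100], strand="+")
        rev = make_reads([1400, 1450, 1500], strand="-")
        from mbdscan.peaks import Peak
        peaks = [Peak("chr1", 900, 1600, 6, 0.001)]
        out = refine_peaks(peaks, fwd + rev, chrom_sizes)
        assert len(out) == 1 and out[0].refined
        assert out[0].wilcoxon_p == pytest.approx(1 / 20)

    def test_require_orientation_drops_unoriented_peaks(self, chrom_sizes):
        fwd = make_reads([1400, 1450, 1500], strand="+")
        rev = make_reads([1000, 1050, 1100], strand="-")
        from mbdscan.peaks import Peak
        peaks = [Peak("chr1", 900, 1600, 6, 0.001)]
        assert refine_peaks(peaks, fwd + rev, chrom_sizes,
                            require_orientation=True) == []


class TestEndToEnd:
    def test_no_reads_gives_empty_peak_list(self, chrom_sizes):
        result = MBDScan([], chrom_sizes).fit()
        assert result.peaks == []

    def test_planted_regions_recovered(self, landscape, enriched_reads):
        result = MBDScan(enriched_reads, landscape.chrom_sizes).fit()
        truth = landscape.regions("control")
        recovered = 0
        for rc, rs, re in truth:
            for p in result.peaks:
                if p.chrom != rc:
                    continue
                ovl = min(re, p.end) - max(rs, p.start)
                if ovl > 0 and ovl >= 0.5 * (re - rs) and ovl >= 0.5 * p.length:
                    recovered += 1
                    break
        assert recovered >= 0.9 * len(truth)

    def test_summary_mentions_fit(self, landscape, enriched_reads):
        result = MBDScan(enriched_reads, landscape.chrom_sizes).fit()
        text = result.summary()
        assert "null" in text and "peaks" in text
        assert f"{result.n_peaks:,}" in text

    def test_null_fit_plot_returns_axis(self, landscape, enriched_reads):
        import matplotlib
        matplotlib.use("Agg")
        result = MBDScan(enriched_reads, landscape.chrom_sizes).fit()
        ax = result.plot_null_fit()
        assert ax.get_xlabel().startswith("reads per 300")
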