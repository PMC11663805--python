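from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdrscan.detection import (CandidateValley, DetectionParams,
                               alpha_signal, call_cdrs, extend_boundaries,
                               filter_by_prominence, find_candidate_valleys,
                               merge_calls, signal_stats, valley_prominence)
from cdrscan.errors import NoAlphaSignalError, UsageError

from conftest import make_profile


# ---------------------------------------------------------------------------
# independent oracles


def oracle_prominence(values, idx):
    """Nearest-strictly-lower formulation of the left/right walk rule."""
    def bound(side):
        if not side:
            return math.inf
        stop = None
        for k, v in enumerate(side):
            if v < values[idx]:
                stop = k
                break
        walked = side if stop is None else side[:stop + 1]
        return max(walked)

    left = bound(list(values[:idx][::-1]))
    right = bound(list(values[idx + 1:]))
    if math.isinf(left) and math.isinf(right):
        return 0.0
    return min(left, right) - values[idx]


def local_minima(values):
    return [i for i in range(len(values))
            if (i == 0 or values[i - 1] >= values[i])
            and (i == len(values) - 1 or values[i + 1] >= values[i])]


def oracle_runs(signal, threshold):
    """Brute-force run scanner over (bin_index, value) pairs."""
    candidates = [(i, v) for i, v in signal if v < threshold]
    runs, current = [], []
    for i, v in candidates:
        if current and i == current[-1][0] + 1:
            current.append((i, v))
        else:
            if current:
                runs.append(current)
            current = [(i, v)]
    if current:
        runs.append(current)
    return runs


# ---------------------------------------------------------------------------


class TestAlphaSignal:
    def test_mask_filter(self):
        prof = make_profile([0.1, 0.2, 0.3, 0.4, 0.5],
                            alpha_mask=[False, True, True, False, True])
        assert [i for i, _ in alpha_signal(prof)] == [1, 2, 4]

    def test_all_alpha_identity(self):
        prof = make_profile([0.1, 0.2, 0.3])
        assert alpha_signal(prof) == [(0, 0.1), (1, 0.2), (2, 0.3)]

    def test_invalid_bins_absent(self):
        prof = make_profile([0.1, None, 0.3])
        assert [i for i, _ in alpha_signal(prof)] == [0, 2]

    def test_no_alpha_raises(self):
        prof = make_profile([0.1, 0.2], alpha_mask=[False, False])
        with pytest.raises(NoAlphaSignalError):
            alpha_signal(prof)

    def test_random_mask_matches_bruteforce_filter(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, size=50)
        mask = rng.uniform(size=50) < 0.6
        prof = make_profile(list(values), alpha_mask=list(mask))
        got = alpha_signal(prof)
        expected = [(i, float(v)) for i, (v, m) in
                    enumerate(zip(values, mask)) if m]
        assert got == expected


class TestSignalStats:
    def test_even_n_median_midpoint(self):
        s = signal_stats(list(enumerate([0.2, 0.8, 0.8, 0.8])))
        assert s.median == pytest.approx(0.8)
        assert s.mean == pytest.approx(0.65)
        assert s.n_alpha_bins == 4

    def test_constant_signal_sd_zero(self):
        s = signal_stats(list(enumerate([0.4] * 7)))
        assert s.sd == pytest.approx(0.0, abs=1e-15)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(1)
        values = [float(v) for v in rng.uniform(0, 1, size=1000)]
        s = signal_stats(list(enumerate(values)))
        ordered = sorted(values)
        median = (ordered[499] + ordered[500]) / 2
        mean = sum(values) / len(values)
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
        assert s.median == pytest.approx(median, abs=1e-12)
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(sd, abs=1e-12)

    def test_empty_signal_rejected(self):
        with pytest.raises(UsageError):
            signal_stats([])


class TestValleyProminence:
    def test_deep_valley_walks_through_shallower(self):
        values = [0.8, 0.2, 0.7, 0.1, 0.9]
        assert valley_prominence(values, 3) == pytest.approx(0.70)

    def test_walk_stops_at_strictly_lower(self):
        values = [0.8, 0.2, 0.7, 0.1, 0.9]
        assert valley_prominence(values, 1) == pytest.approx(0.50)

    def test_monotone_decreasing_edge(self):
        values = [0.9, 0.7, 0.5, 0.3]
        assert valley_prominence(values, 3) == pytest.approx(0.6)

    def test_single_element(self):
        assert valley_prominence([0.5], 0) == 0.0

    def test_not_local_minimum_rejected(self):
        with pytest.raises(UsageError):
            valley_prominence([0.1, 0.5, 0.9], 1)

    def test_exhaustive_small_signals_match_oracle(self):
        grid = [0.1, 0.5, 0.9]
        for n in range(1, 6):
            for values in itertools.product(grid, repeat=n):
                for idx in local_minima(values):
                    assert valley_prominence(list(values), idx) == \
                        pytest.approx(oracle_prominence(values, idx))

    @given(st.lists(st.sampled_from([round(0.1 * k, 1)
                                     for k in range(1, 10)]),
                    min_size=1, max_size=12))
    @settings(max_examples=300, deadline=None)
    def test_property_matches_oracle(self, values):
        for idx in local_minima(values):
            assert valley_prominence(values, idx) == \
                pytest.approx(oracle_prominence(values, idx))


class TestFindCandidateValleys:
    def test_median_relative_threshold_example(self):
        # median 0.75, depth 0.34 -> threshold 0.495
        values = [0.70, 0.45, 0.40, 0.70, 0.80, 0.80, 0.80]
        signal = list(enumerate(values))
        stats = signal_stats(signal)
        stats = type(stats)(median=0.75, mean=stats.mean, sd=stats.sd,
                            n_alpha_bins=stats.n_alpha_bins)
        valleys = find_candidate_valleys(signal, stats, DetectionParams())
        assert len(valleys) == 1
        assert valleys[0].bin_index_range == (1, 2)
        assert valleys[0].min_value == pytest.approx(0.40)
        assert valleys[0].min_index == 2

    def test_flat_signal_no_candidates(self):
        signal = list(enumerate([0.6] * 10))
        stats = signal_stats(signal)
        assert find_candidate_valleys(signal, stats,
                                      DetectionParams()) == []

    def test_two_planted_runs_split_by_high_bin(self):
        values = [0.8] * 5 + [0.2, 0.2] + [0.8] + [0.3, 0.2] + [0.8] * 5
        signal = list(enumerate(values))
        stats = signal_stats(signal)
        valleys = find_candidate_valleys(signal, stats, DetectionParams())
        assert [v.bin_index_range for v in valleys] == [(5, 6), (8, 9)]

    def test_genomic_gap_splits_run(self):
        # bins 3 and 5 are candidates but bin 4 is missing from the signal
        signal = [(0, 0.8), (1, 0.8), (3, 0.1), (5, 0.1), (6, 0.8),
                  (7, 0.8), (8, 0.8)]
        stats = signal_stats(signal)
        valleys = find_candidate_valleys(signal, stats, DetectionParams())
        assert [v.bin_index_range for v in valleys] == [(3, 3), (5, 5)]

    def test_tie_breaks_leftmost(self):
        values = [0.8] * 4 + [0.2, 0.2, 0.2] + [0.8] * 4
        signal = list(enumerate(values))
        stats = signal_stats(signal)
        (valley,) = find_candidate_valleys(signal, stats, DetectionParams())
        assert valley.min_index == 4

    def test_random_signals_match_run_scanner_oracle(self):
        rng = np.random.default_rng(7)
        params = DetectionParams()
        for _ in range(100):
            n = int(rng.integers(1, 40))
            values = np.round(rng.uniform(0, 1, size=n), 2)
            mask = rng.uniform(size=n) < 0.8
            signal = [(i, float(v)) for i, (v, m)
                      in enumerate(zip(values, mask)) if m]
            if not signal:
                continue
            stats = signal_stats(signal)
            threshold = params.candidate_threshold(stats.median)
            expected = oracle_runs(signal, threshold)
            got = find_candidate_valleys(signal, stats, params)
            assert [v.bin_index_range for v in got] == \
                [(r[0][0], r[-1][0]) for r in expected]
            for v, run in zip(got, expected):
                assert v.min_value == pytest.approx(
                    min(x for _, x in run))


class TestFilterByProminence:
    def _stats(self, median):
        from cdrscan.detection import SignalStats
        return SignalStats(median=median, mean=median, sd=0.0, n_alpha_bins=1)

    def _valley(self, prom):
        return CandidateValley(bin_index_range=(0, 0), min_index=0,
                               min_value=0.1, prominence=prom)

    def test_cutoff_arithmetic(self):
        # median 0.75 -> cutoff 0.225
        stats = self._stats(0.75)
        kept = filter_by_prominence(
            [self._valley(0.50), self._valley(0.10)], [], stats,
            DetectionParams())
        assert [v.prominence for v in kept] == [0.50]

    def test_exact_cutoff_kept(self):
        stats = self._stats(0.75)
        cutoff = DetectionParams().prominence_cutoff(0.75)
        kept = filter_by_prominence([self._valley(cutoff)], [], stats,
                                    DetectionParams())
        assert len(kept) == 1

    def test_monotone_in_prominence_fraction(self):
        stats = self._stats(0.6)
        valleys = [self._valley(p) for p in (0.05, 0.1, 0.2, 0.4, 0.8)]
        counts = [len(filter_by_prominence(
            valleys, [], stats, DetectionParams(prominence_fraction=pf)))
            for pf in (0.0, 0.1, 0.3, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestExtendBoundaries:
    def _stats(self, mean, sd, median=0.7):
        from cdrscan.detection import SignalStats
        return SignalStats(median=median, mean=mean, sd=sd, n_alpha_bins=1)

    def test_mean_minus_sd_extension(self):
        # T = 0.70 - 0.10 = 0.60; right neighbors 0.55, 0.58, 0.65
        values = [0.8, 0.8, 0.3, 0.55, 0.58, 0.65, 0.8]
        prof = make_profile(values)
        valley = CandidateValley(bin_index_range=(2, 2), min_index=2,
                                 min_value=0.3)
        out = extend_boundaries(valley, prof, self._stats(0.70, 0.10),
                                DetectionParams())
        assert out.bin_index_range == (2, 4)

    def test_multiplier_zero_never_shrinks(self):
        values = [0.8, 0.65, 0.3, 0.65, 0.68, 0.8]
        prof = make_profile(values)
        valley = CandidateValley(bin_index_range=(2, 2), min_index=2,
                                 min_value=0.3)
        stats = self._stats(0.70, 0.10)
        with_sd = extend_boundaries(valley, prof, stats, DetectionParams())
        without = extend_boundaries(valley, prof, stats,
                                    DetectionParams(edge_sd_multiplier=0.0))
        assert without.bin_index_range[0] <= with_sd.bin_index_range[0]
        assert without.bin_index_range[1] >= with_sd.bin_index_range[1]
        assert without.bin_index_range == (1, 4)

    def test_never_crosses_invalid_or_non_alpha(self):
        values = [0.1, None, 0.1, 0.3, 0.1, 0.1]
        mask = [True, True, True, True, True, False]
        prof = make_profile(values, alpha_mask=mask)
        valley = CandidateValley(bin_index_range=(3, 3), min_index=3,
                                 min_value=0.3)
        out = extend_boundaries(valley, prof, self._stats(0.70, 0.10),
                                DetectionParams())
        assert out.bin_index_range == (2, 4)

    def test_scan_oracle_on_sigmoid_edges(self):
        rng = np.random.default_rng(4)
        x = np.arange(60)
        dip = 0.8 - 0.7 / (1 + np.exp((np.abs(x - 30) - 8)))
        values = list(np.round(dip + rng.normal(0, 0.01, size=60), 3))
        prof = make_profile(values)
        stats = signal_stats(list(enumerate(values)))
        params = DetectionParams()
        valley = CandidateValley(bin_index_range=(30, 30), min_index=30,
                                 min_value=values[30])
        out = extend_boundaries(valley, prof, stats, params)
        threshold = stats.mean - stats.sd
        lo, hi = out.bin_index_range
        # brute-force scan: the contiguous below-threshold block around 30
        exp_lo = 30
        while exp_lo > 0 and values[exp_lo - 1] < threshold:
            exp_lo -= 1
        exp_hi = 30
        while exp_hi < 59 and values[exp_hi + 1] < threshold:
            exp_hi += 1
        assert (lo, hi) == (exp_lo, exp_hi)


def _v(lo, hi, min_value=0.1, prom=0.5):
    return CandidateValley(bin_index_range=(lo, hi), min_index=lo,
                           min_value=min_value, prominence=prom)


class TestMergeCalls:
    def test_touching_calls_merge(self):
        out = merge_calls([_v(0, 3), _v(3, 6)], DetectionParams())
        assert len(out) == 1 and out[0].bin_index_range == (0, 6)

    def test_distant_calls_unchanged(self):
        out = merge_calls([_v(0, 3), _v(14, 16)], DetectionParams())
        assert [c.bin_index_range for c in out] == [(0, 3), (14, 16)]

    def test_gap_rule(self):
        # separated by exactly one bin -> merged with default gap 1
        out = merge_calls([_v(0, 3), _v(5, 7)], DetectionParams())
        assert [c.bin_index_range for c in out] == [(0, 7)]
        out2 = merge_calls([_v(0, 3), _v(6, 7)],
                           DetectionParams(merge_gap_bins=1))
        assert len(out2) == 2

    def test_deepest_member_wins(self):
        a = _v(0, 2, min_value=0.3, prom=0.2)
        b = _v(3, 5, min_value=0.1, prom=0.6)
        (m,) = merge_calls([a, b], DetectionParams())
        assert m.min_value == 0.1 and m.min_index == 3
        assert m.prominence == 0.6

    def test_union_find_oracle(self):
        rng = np.random.default_rng(6)
        params = DetectionParams(merge_gap_bins=1)
        for _ in range(50):
            calls = []
            for _ in range(int(rng.integers(1, 12))):
                lo = int(rng.integers(0, 60))
                calls.append(_v(lo, lo + int(rng.integers(0, 8))))
            got = merge_calls(calls, params)
            # oracle: union of padded intervals
            covered = set()
            for c in calls:
                lo, hi = c.bin_index_range
                covered.update(range(lo, hi + 1))
            # two ranges merge when gap <= 1: close 1-bin holes between
            # covered bins
            blocks = []
            for i in sorted(covered):
                if blocks and i - blocks[-1][1] - 1 <= params.merge_gap_bins:
                    blocks[-1][1] = max(blocks[-1][1], i)
                else:
                    blocks.append([i, i])
            assert [tuple(c.bin_index_range) for c in got] == \
                [tuple(b) for b in blocks]


class TestCallCdrs:
    def test_planted_dip_single_call(self):
        values = [0.85] * 40 + [0.5, 0.15, 0.1, 0.1, 0.2, 0.6] + [0.85] * 40
        prof = make_profile(values)
        calls = call_cdrs(prof)
        assert len(calls) == 1
        c = calls[0]
        assert c.interval.start <= 41 * 5000
        assert c.interval.end >= 45 * 5000
        assert c.min_freq == pytest.approx(0.1)
        assert c.min_freq < c.region_median

    def test_hypermethylated_region_no_calls(self):
        rng = np.random.default_rng(3)
        values = list(0.85 + rng.normal(0, 0.01, size=100))
        prof = make_profile(values)
        assert call_cdrs(prof) == []

    def test_two_distant_dips_two_calls(self):
        dip = [0.4, 0.1, 0.1, 0.4]
        values = [0.85] * 20 + dip + [0.85] * 100 + dip + [0.85] * 20
        prof = make_profile(values)
        calls = call_cdrs(prof)
        assert len(calls) == 2
        assert calls[0].interval.end < calls[1].interval.start

    def test_calls_within_region_and_below_threshold(self):
        rng = np.random.default_rng(8)
        values = list(np.clip(0.8 + rng.normal(0, 0.25, size=200), 0, 1))
        prof = make_profile(values)
        params = DetectionParams()
        calls = call_cdrs(prof, params)
        for c in calls:
            assert c.interval.start >= prof.region.start
            assert c.interval.end <= prof.region.end
            assert c.min_freq < params.candidate_threshold(c.region_median)

    def test_determinism(self):
        rng = np.random.default_rng(10)
        values = list(np.clip(0.8 + rng.normal(0, 0.3, size=150), 0, 1))
        prof = make_profile(values)
        a = call_cdrs(prof)
        b = call_cdrs(prof)
        assert a == b

    def test_propagates_no_alpha(self):
        prof = make_profile([0.5] * 5, alpha_mask=[False] * 5)
        with pytest.raises(NoAlphaSignalError):
            call_cdrs(prof)


class TestDetectionParams:
    @pytest.mark.parametrize("kwargs", [
        {"bin_size": 0}, {"depth_fraction": 0.0}, {"depth_fraction": 1.0},
        {"prominence_fraction": 1.0}, {"edge_sd_multiplier": -1.0},
        {"merge_gap_bins": -1},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(UsageError):
            DetectionParams(**kwargs)

    def test_absolute_mode(self):
        p = DetectionParams(absolute_thresholds=True)
        assert p.candidate_threshold(0.9) == pytest.approx(0.34)
        assert p.prominence_cutoff(0.9) == pytest.approx(0.30)
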