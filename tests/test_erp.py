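"""Coherent averaging, windowed peak analysis, and the rank statistics."""

import itertools

import numpy as np
import pytest

from p300screen.erp import (
    CoherentAverage,
    bonferroni,
    coherent_average,
    compare_windows,
    group_peak_test,
    peak_in_window,
    window_indices,
)
from p300screen.errors import ConfigurationError
from p300screen.preprocessing import Epoch
from p300screen.sequencer import StimulusEvent

FS = 512.0


def _epoch(samples):
    event = StimulusEvent(0.0, 0.125, 0, "flash")
    e = Epoch(np.asarray(samples, dtype=float), event)
    e.standardized = True
    return e


def _avg(waveform, n=1, condition="target"):
    return CoherentAverage(np.asarray(waveform, dtype=float), n, condition)


def _gaussian(latency_ms, width_ms=45.0, amp=1.0, n=307):
    t = np.arange(n) / FS * 1000.0
    return amp * np.exp(-((t - latency_ms) ** 2) / (2 * width_ms**2))


class TestWindowIndices:
    def test_default_window_is_samples_77_to_230(self):
        idx = window_indices((150.0, 450.0), FS, 307)
        assert idx[0] == 77 and idx[-1] == 230


class TestCoherentAverage:
    def test_identical_epochs_average_to_channel_mean(self, rng):
        samples = rng.standard_normal((8, 307))
        avg = coherent_average([_epoch(samples)] * 5, "target")
        np.testing.assert_allclose(avg.waveform, samples.mean(axis=0))
        assert avg.n_epochs == 5

    def test_weighted_linearity_over_disjoint_sets(self, rng):
        a = [_epoch(rng.standard_normal((8, 307))) for _ in range(3)]
        b = [_epoch(rng.standard_normal((8, 307))) for _ in range(5)]
        combined = coherent_average(a + b, "target").waveform * 8
        parts = coherent_average(a, "target").waveform * 3 + coherent_average(
            b, "target"
        ).waveform * 5
        np.testing.assert_allclose(combined, parts)

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigurationError):
            coherent_average([], "target")


class TestPeakInWindow:
    def test_gaussian_peak_recovered_at_its_latency(self):
        result = peak_in_window(_avg(_gaussian(310.0)))
        assert result.latency_ms == pytest.approx(310.0, abs=1000.0 / FS)

    @pytest.mark.parametrize("latency", [200.0, 310.0, 440.0])
    def test_latency_unbiased_on_clean_templates(self, latency):
        result = peak_in_window(_avg(_gaussian(latency)))
        assert result.latency_ms == pytest.approx(latency, abs=1000.0 / FS)

    def test_monotone_decreasing_peaks_at_left_edge(self):
        result = peak_in_window(_avg(np.linspace(1.0, 0.0, 307)))
        assert result.latency_ms == pytest.approx(77 / FS * 1000.0)

    def test_ties_break_toward_earlier_latency(self):
        wave = np.zeros(307)
        wave[[100, 200]] = 3.0
        result = peak_in_window(_avg(wave))
        assert result.latency_ms == pytest.approx(100 / FS * 1000.0)


class TestCompareWindows:
    def test_identical_waveforms_do_not_reject(self, rng):
        wave = rng.standard_normal(307)
        _, p = compare_windows(_avg(wave), _avg(wave, condition="nontarget"))
        assert p > 0.9

    def test_large_offset_fully_separates_ranks(self, rng):
        base = rng.standard_normal(307)
        u, p = compare_windows(_avg(base + 100.0), _avg(base, condition="nontarget"))
        n = 154
        assert min(u, n * n - u) == 0.0
        assert p < 0.005

    def test_u_matches_pair_counting_oracle(self, rng):
        t = _avg(rng.standard_normal(307))
        nt = _avg(rng.standard_normal(307), condition="nontarget")
        window = (150.0, 168.0)  # ten samples: indices 77..86
        u, p = compare_windows(t, nt, window)
        idx = window_indices(window, FS, 307)
        x, y = t.waveform[idx], nt.waveform[idx]
        pairs = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        assert u == pytest.approx(pairs)

    def test_p_close_to_exhaustive_rank_enumeration(self, rng):
        """Two-sided p agrees with the exact rank-sum null distribution,
        enumerated by dynamic programming, on a ten-sample window."""
        t = _avg(rng.standard_normal(307))
        nt = _avg(rng.standard_normal(307), condition="nontarget")
        window = (150.0, 168.0)
        u, p = compare_windows(t, nt, window)

        n = m = 10
        # counts[k][s]: subsets of {1..n+m} of size k with rank-sum s
        counts = np.zeros((n + 1, (n + m) * (n + m + 1) // 2 + 1), dtype=object)
        counts[0][0] = 1
        for rank in range(1, n + m + 1):
            for k in range(min(rank, n), 0, -1):
                counts[k][rank:] = counts[k][rank:] + counts[k - 1][:-rank]
        dist = counts[n]
        total = sum(dist)
        # U = ranksum(x) - n(n+1)/2
        u_vals = np.arange(len(dist)) - n * (n + 1) // 2
        p_low = sum(dist[u_vals <= u]) / total
        p_high = sum(dist[u_vals >= u]) / total
        p_exact = min(1.0, 2 * min(p_low, p_high))
        assert p == pytest.approx(float(p_exact), abs=0.02)


class TestGroupPeakTest:
    def test_uniform_dominance_gives_zero_statistic(self, rng):
        nt = rng.standard_normal(8)
        w, p = group_peak_test(nt + np.linspace(1, 2, 8), nt)
        assert w == 0.0
        assert p < 0.01

    def test_identical_pairs_are_degenerate(self):
        w, p = group_peak_test([1.0] * 6, [1.0] * 6)
        assert (w, p) == (0.0, 1.0)

    def test_matches_exhaustive_signed_rank_enumeration(self, rng):
        t = rng.standard_normal(6)
        nt = rng.standard_normal(6)
        w_obs, p_obs = group_peak_test(t, nt)
        diffs = t - nt
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        stats = []
        for signs in itertools.product([1, -1], repeat=6):
            t_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            stats.append(min(t_plus, ranks.sum() - t_plus))
        observed = min(
            sum(r for r, d in zip(ranks, diffs) if d > 0),
            sum(r for r, d in zip(ranks, diffs) if d < 0),
        )
        p_exact = np.mean([s <= observed for s in stats])
        assert w_obs == pytest.approx(observed)
        assert p_obs == pytest.approx(p_exact, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            group_peak_test([1.0] * 6, [1.0] * 5)


class TestOnStudy:
    """Statistical behavior on the 20-subject default-condition study."""

    def test_target_peaks_dominate_nontarget_peaks(self, study):
        _, results = study
        w, p = group_peak_test(
            [r.target_peak for r in results], [r.nontarget_peak for r in results]
        )
        assert w == 0.0
        assert p < 0.001

    def test_window_comparison_detects_target_structure(self, study):
        """Pooled-sample MWUT on z-scored averages is a weak detector (the
        epoch-level standardization balances the window around zero), but it
        must still reject well above the nominal rate under the alternative."""
        _, results = study
        p_raw = np.array([r.mwut_p for r in results])
        assert np.median(p_raw) < 0.2
        assert (p_raw < 0.05).mean() >= 0.25

    def test_target_peak_latency_in_p300_range(self, study):
        _, results = study
        latencies = [
            r.erp_report.query("condition == 'target'")["peak_latency_ms"].iloc[0]
            for r in results
        ]
        assert 250 <= np.median(latencies) <= 370


def test_bonferroni_caps_at_one():
    np.testing.assert_allclose(
        bonferroni([0.001, 0.5, 0.9]), [0.003, 1.0, 1.0]
    )
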