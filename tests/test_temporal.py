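"""Temporal defocus signals, zero crossings, and decision strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from acuitysim.optics import apply_otf, load_hoa_population, otf_image_grid
from acuitysim.temporal import (
    DefocusSignal,
    EpochConfig,
    Strategy,
    defocus_series,
    least_defocus_bin,
    strategy_sample_indices,
    zero_crossing_interval,
    zero_crossing_probability,
)


class TestDefocusSeries:
    def test_constant_when_amplitude_zero(self):
        sig = DefocusSignal(0.0, 1.0, dc_offset_d=0.75)
        s = defocus_series(sig, 123.4)
        assert s.shape == (300,)
        np.testing.assert_allclose(s, 0.75)

    def test_closed_form_sample(self):
        # A=2 D at 2 Hz starting at t0=0: quarter period at 125 ms -> +2 D
        sig = DefocusSignal(2.0, 2.0)
        s = defocus_series(sig, 0.0)
        assert s[125] == pytest.approx(2.0, abs=1e-9)

    def test_bounds_over_random_phases(self):
        sig = DefocusSignal(1.5, 0.5, dc_offset_d=0.25)
        rng = np.random.default_rng(0)
        for t0 in rng.uniform(0, 2000, size=200):
            s = defocus_series(sig, t0)
            assert s.min() >= 0.25 - 1.5 - 1e-9
            assert s.max() <= 0.25 + 1.5 + 1e-9

    def test_invalid_signal(self):
        with pytest.raises(ValueError):
            DefocusSignal(-1.0, 1.0)
        with pytest.raises(ValueError):
            DefocusSignal(1.0, 0.0)


def mc_zero_crossing(freq, duration, n, seed, offset=0.0, amplitude=1.0):
    """Monte-Carlo oracle: place windows uniformly, check for a zero."""
    rng = np.random.default_rng(seed)
    period = 1.0 / freq
    t0 = rng.uniform(0.0, period, size=n)
    t = np.linspace(0.0, duration, 400)
    d = offset + amplitude * np.sin(2 * np.pi * freq * (t0[:, None] + t[None, :]))
    sign_change = np.any(np.diff(np.signbit(d), axis=1), axis=1) | np.any(d == 0, axis=1)
    return sign_change.mean()


class TestZeroCrossing:
    @pytest.mark.parametrize(
        "freq,expected", [(2.0, 1.0), (1.0, 0.6), (0.5, 0.30), (0.25, 0.15)]
    )
    def test_analytic_values_for_study_frequencies(self, freq, expected):
        assert zero_crossing_probability(freq, 0.3) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("freq", [0.25, 0.5, 1.0, 2.0])
    def test_monte_carlo_agreement_within_three_se(self, freq):
        n = 100_000
        p_hat = mc_zero_crossing(freq, 0.3, n, seed=7)
        p = zero_crossing_probability(freq, 0.3)
        se = max(np.sqrt(p * (1 - p) / n), 1e-4)
        assert abs(p_hat - p) <= 3 * se

    def test_half_period_between_zeros(self):
        assert zero_crossing_interval(2.0) == pytest.approx(0.250, abs=1e-12)
        assert zero_crossing_interval(0.25) == pytest.approx(2.0)

    def test_offset_beyond_amplitude_has_no_zeros(self):
        assert zero_crossing_probability(2.0, 0.3, amplitude_d=0.5, dc_offset_d=0.6) == 0.0

    def test_offset_within_amplitude_matches_monte_carlo(self):
        p = zero_crossing_probability(2.0, 0.05, amplitude_d=1.0, dc_offset_d=0.5)
        p_hat = mc_zero_crossing(2.0, 0.05, 100_000, seed=11, offset=0.5, amplitude=1.0)
        assert p == pytest.approx(p_hat, abs=3 * np.sqrt(p_hat * (1 - p_hat) / 100_000))

    @given(
        freq=st.floats(0.1, 5.0),
        dur=st.floats(0.01, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_probability_bounds_and_monotonicity_in_duration(self, freq, dur):
        p1 = zero_crossing_probability(freq, dur)
        p2 = zero_crossing_probability(freq, dur * 1.5)
        assert 0.0 <= p1 <= 1.0
        assert p2 >= p1 - 1e-12


class TestStrategies:
    def test_average_early_late_index_windows(self):
        s = defocus_series(DefocusSignal(1.0, 1.0), 0.0)
        assert len(strategy_sample_indices(s, "average")) == 300
        np.testing.assert_array_equal(strategy_sample_indices(s, "early"), np.arange(100))
        np.testing.assert_array_equal(
            strategy_sample_indices(s, "late"), np.arange(200, 300)
        )

    def test_least_bin_minimizes_mean_absolute_defocus(self):
        # exhaustive over a dense grid of epoch placements
        sig = DefocusSignal(2.0, 2.0)
        epoch = EpochConfig()
        for t0 in np.linspace(0.0, 500.0, 101):
            s = defocus_series(sig, t0, epoch)
            bins = np.abs(s).reshape(6, 50).mean(axis=1)
            b = least_defocus_bin(s, epoch)
            assert bins[b] <= bins.min() + 1e-12
            # 2 Hz guarantees a zero crossing in the epoch.  Worst case puts
            # the zero at a bin edge: mean |A sin| over the adjacent bin is
            # A (1 - cos(w b)) / (w b) = 0.608 D for A=2, b=50 ms.
            assert bins[b] < 0.61

    def test_degenerate_constant_series_all_strategies_agree(self):
        s = np.full(300, 1.0)
        sets = {
            strat: tuple(np.sort(strategy_sample_indices(s, strat)))
            for strat in ("average", "least", "early", "late")
        }
        # different windows, but every selected sample has the same defocus
        for idx in sets.values():
            np.testing.assert_allclose(s[list(idx)], 1.0)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            strategy_sample_indices(np.zeros(300), "newest")

    def test_mixed_requires_rng_and_is_uniform(self):
        s = defocus_series(DefocusSignal(1.0, 0.5), 10.0)
        with pytest.raises(ValueError):
            strategy_sample_indices(s, "mixed")
        rng = np.random.default_rng(21)
        counts = {300: 0, 50: 0, "early": 0, "late": 0}
        n = 10_000
        sizes = []
        for _ in range(n):
            idx = strategy_sample_indices(s, Strategy.MIXED, rng=rng)
            if len(idx) == 300:
                key = 300
            elif len(idx) == 50:
                key = 50
            elif idx[0] == 0:
                key = "early"
            else:
                key = "late"
            counts[key] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.001, counts


class TestStrategyImageEquivalence:
    def test_average_image_equals_filter_by_mean_otf(self, engine):
        """Mean of per-sample filtered images == image filtered by mean OTF."""
        from acuitysim.optotypes import build_bank

        img = build_bank()[("D", 0.6)]
        hoa = load_hoa_population()
        defoci = [-0.4, 0.1, 0.7]
        otfs = [otf_image_grid(hoa.with_defocus(d)) for d in defoci]
        mean_of_filtered = np.mean([apply_otf(img, O) for O in otfs], axis=0)
        filtered_by_mean = apply_otf(img, np.mean(otfs, axis=0))
        assert np.abs(mean_of_filtered - filtered_by_mean).max() < 1e-10

    def test_engine_effective_image_matches_float64_reference(self, engine):
        """The quantized complex64 fast path tracks the exact pipeline."""
        from acuitysim.neural import apply_ntf
        from acuitysim.optotypes import build_bank

        series = defocus_series(DefocusSignal(1.0, 0.5), 321.0)
        idx = strategy_sample_indices(series, "least")
        img = build_bank()[("O", 0.4)]
        # exact route: quantize identically, then average float64 OTFs
        q = np.rint(series[idx] / engine.quant_step_d) * engine.quant_step_d
        otfs = [otf_image_grid(engine.hoa.with_defocus(d)) for d in np.unique(q)]
        counts = [np.sum(np.unique(q) == u) for u in np.unique(q)]
        mean_otf = np.average(otfs, axis=0, weights=counts)
        ref = apply_ntf(apply_otf(img, mean_otf), engine.render_cfg)
        fast = engine.effective_test_image("O", 0.4, series[idx])
        # complex64 OTF cache rounding; far below the noise SD of 0.38
        assert np.abs(ref - fast).max() < 1e-3
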