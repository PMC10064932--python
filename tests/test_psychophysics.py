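"""Constant-stimuli sessions, psychometric fitting, and regressions."""

import numpy as np
import pytest
from scipy.stats import norm

from acuitysim.psychophysics import (
    CHANCE_RATE_26AFC,
    PsychometricData,
    SessionConfig,
    SessionError,
    fit_psychometric,
    initial_center,
    monte_carlo_variance,
    regression_by_frequency,
    run_constant_stimuli,
)
from acuitysim.temporal import DefocusSignal


def synthetic_data(mu, sigma, rng, levels=None, reps=10):
    levels = levels if levels is not None else [round(-0.2 + 0.1 * i, 1) for i in range(11)]
    p = norm.cdf((np.asarray(levels) - mu) / sigma)
    k = rng.binomial(reps, p)
    return PsychometricData(
        levels=tuple(levels),
        n_correct=tuple(int(x) for x in k),
        n_presented=tuple([reps] * len(levels)),
    )


class TestFit:
    def test_parameter_recovery_over_200_seeds(self):
        """Binomial data from a known cumulative Gaussian: the ML fit
        recovers mu within 0.01 and sigma within 0.02 on average."""
        mus, sigmas = [], []
        for seed in range(200):
            data = synthetic_data(0.30, 0.10, np.random.default_rng(seed))
            fit = fit_psychometric(data)
            mus.append(fit.mu)
            sigmas.append(fit.sigma)
        assert np.mean(mus) == pytest.approx(0.30, abs=0.01)
        assert np.mean(sigmas) == pytest.approx(0.10, abs=0.02)

    def test_threshold_criterion_offset(self):
        data = synthetic_data(0.30, 0.10, np.random.default_rng(3))
        fit = fit_psychometric(data)
        assert fit.threshold - fit.mu == pytest.approx(fit.sigma * norm.ppf(0.519), abs=1e-9)
        assert norm.ppf(0.519) == pytest.approx(0.0476, abs=2e-4)

    def test_all_correct_data_flagged_degenerate(self):
        data = PsychometricData(
            levels=tuple(round(0.1 * i, 1) for i in range(11)),
            n_correct=(10,) * 11,
            n_presented=(10,) * 11,
        )
        fit = fit_psychometric(data)
        assert fit.degenerate and not fit.converged

    def test_guess_rate_mode_uses_exact_26afc_chance(self):
        assert CHANCE_RATE_26AFC == 1.0 / 26.0
        data = synthetic_data(0.30, 0.10, np.random.default_rng(5))
        fit = fit_psychometric(data, guess_rate=CHANCE_RATE_26AFC)
        assert fit.guess_rate == CHANCE_RATE_26AFC
        # criterion maps through the corrected asymptotes
        crit = (0.519 - CHANCE_RATE_26AFC) / (1 - CHANCE_RATE_26AFC)
        assert fit.threshold - fit.mu == pytest.approx(fit.sigma * norm.ppf(crit), abs=1e-9)


class TestMonteCarlo:
    def test_extreme_proportions_give_zero_variance(self):
        data = PsychometricData(
            levels=tuple(round(-0.2 + 0.1 * i, 1) for i in range(11)),
            n_correct=(0, 0, 0, 0, 0, 10, 10, 10, 10, 10, 10),
            n_presented=(10,) * 11,
        )
        fit = fit_psychometric(data)
        a_sd, s_sd = monte_carlo_variance(data, fit, np.random.default_rng(0))
        assert a_sd == pytest.approx(0.0, abs=1e-12)
        assert s_sd == pytest.approx(0.0, abs=1e-12)

    def test_steep_function_yields_smaller_acuity_sd(self):
        rng = np.random.default_rng(8)
        steep = synthetic_data(0.30, 0.05, rng)
        shallow = synthetic_data(0.30, 0.25, rng)
        sd_steep, _ = monte_carlo_variance(steep, fit_psychometric(steep), np.random.default_rng(1))
        sd_shallow, _ = monte_carlo_variance(
            shallow, fit_psychometric(shallow), np.random.default_rng(1)
        )
        assert sd_steep < sd_shallow

    def test_seeded_reproducibility(self):
        data = synthetic_data(0.30, 0.10, np.random.default_rng(9))
        fit = fit_psychometric(data)
        a1 = monte_carlo_variance(data, fit, np.random.default_rng(4), n_rep=30)
        a2 = monte_carlo_variance(data, fit, np.random.default_rng(4), n_rep=30)
        assert a1 == a2


class TestRegression:
    def test_closed_form_four_point_ols(self):
        # hand-computed OLS: Sxy = 0.39375, Sxx = 1.796875 over these points
        acu = {0.25: 0.0, 0.5: 0.1, 1.0: 0.2, 2.0: 0.4}
        fit = regression_by_frequency(acu)
        assert fit["slope"] == pytest.approx(0.39375 / 1.796875, abs=1e-9)
        assert fit["intercept"] == pytest.approx(0.175 - (0.39375 / 1.796875) * 0.9375, abs=1e-9)
        assert fit["r2"] == pytest.approx(0.9861, abs=1e-3)

    def test_collinear_points_give_perfect_fit(self):
        acu = {a: 0.05 + 0.2 * a for a in (0.25, 0.5, 1.0, 2.0)}
        fit = regression_by_frequency(acu)
        assert fit["slope"] == pytest.approx(0.2, abs=1e-12)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_acuities_flagged(self):
        fit = regression_by_frequency({0.25: 0.1, 0.5: 0.1, 1.0: 0.1, 2.0: 0.1})
        assert fit["slope"] == 0.0 and fit["r2"] is None

    def test_missing_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            regression_by_frequency({1.0: 0.2})


class TestSession:
    def test_session_structure_and_determinism(self, engine):
        sig = DefocusSignal(0.5, 2.0)
        data1 = run_constant_stimuli(engine, sig, "least", np.random.default_rng(77))
        data2 = run_constant_stimuli(engine, sig, "least", np.random.default_rng(77))
        assert data1 == data2
        assert sum(data1.n_presented) == 110
        assert len(data1.levels) == 11
        assert all(c <= p for c, p in zip(data1.n_correct, data1.n_presented))

    def test_initial_center_tracks_expected_defocus(self):
        cfg = SessionConfig()
        levels = tuple(round(-0.5 + 0.1 * i, 1) for i in range(19))
        c0 = initial_center(DefocusSignal(0.0, 1.0), levels, cfg)
        c2 = initial_center(DefocusSignal(0.0, 1.0, dc_offset_d=2.0), levels, cfg)
        assert c0 == 0.0
        assert c2 == pytest.approx(0.7)  # 0.35/D * 2 D
        assert c2 + 0.5 <= max(levels)

    def test_large_static_defocus_triggers_recentering(self, engine):
        """A window centered at baseline acuity under 2 D of static defocus
        floors out: the first 28 trials all fail and the session recenters."""
        sig = DefocusSignal(0.0, 1.0, dc_offset_d=2.0)
        cfg = SessionConfig(center_slope_per_d=0.0)  # force a bad initial center
        # the floor sits at the 1-in-10 guess rate, so a 28-trial miss streak
        # is seed-dependent; this seed produces one
        data = run_constant_stimuli(engine, sig, "average", np.random.default_rng(1), cfg)
        assert data.restarts >= 1
        assert data.levels[0] >= -0.3  # window moved toward larger letters
        assert sum(data.n_presented) == 110

    def test_recentering_exhaustion_raises(self):
        """Noise-free, defocus-free observer is at ceiling for every size,
        so the session keeps recentering downward until the bank edge."""
        from acuitysim.model import AcuityEngine
        from acuitysim.neural import NoiseConfig

        eng = AcuityEngine(noise_cfg=NoiseConfig(variance=0.0))
        sig = DefocusSignal(0.0, 1.0)
        with pytest.raises(SessionError):
            run_constant_stimuli(eng, sig, "average", np.random.default_rng(2))
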