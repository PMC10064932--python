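"""Simulated method-of-constant-stimuli sessions and psychometric fitting.

A session presents 11 optotype sizes (0.1 logMAR apart) 10 times each in
random order (110 trials).  If the first 25% of trials (28) are all correct
or all incorrect, the session is aborted and restarted with the size window
recentered by -0.2 or +0.2 logMAR respectively.  Per-size proportions
correct are fitted with a cumulative Gaussian by maximum likelihood
(Nelder-Mead); the threshold acuity is read at 51.9% correct and the fitted
standard deviation is the precision measure.  Within-session uncertainty
comes from a 100-repetition Monte Carlo resampling of the binomial counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import linregress, norm

from .model import AcuityEngine
from .temporal import DefocusSignal, Strategy

__all__ = [
    "CHANCE_RATE_26AFC",
    "SessionConfig",
    "SessionError",
    "PsychometricData",
    "PsychometricFit",
    "ConditionResult",
    "run_constant_stimuli",
    "fit_psychometric",
    "monte_carlo_variance",
    "regression_by_frequency",
    "initial_center",
]

#: Chance rate of the 26-alternative forced-choice letter task (the human
#: task: observers did not know only 10 letters were used).
CHANCE_RATE_26AFC = 1.0 / 26.0

#: Threshold criterion on the fitted psychometric function.
THRESHOLD_CRITERION = 0.519


class SessionError(RuntimeError):
    """Raised when the recentering rule exhausts the size range."""


@dataclass(frozen=True)
class SessionConfig:
    n_sizes: int = 11
    reps_per_size: int = 10
    size_step: float = 0.1
    recenter_fraction: float = 0.25
    recenter_step: float = 0.2
    max_restarts: int = 5
    #: expected acuity loss per diopter used only to seed the size window
    center_slope_per_d: float = 0.35

    @property
    def n_trials(self) -> int:
        return self.n_sizes * self.reps_per_size

    @property
    def recenter_after(self) -> int:
        return math.ceil(self.recenter_fraction * self.n_trials)


@dataclass(frozen=True)
class PsychometricData:
    """Per-size correct counts plus the condition that produced them."""

    levels: tuple[float, ...]
    n_correct: tuple[int, ...]
    n_presented: tuple[int, ...]
    condition: dict = field(default_factory=dict)
    restarts: int = 0

    def proportions(self) -> np.ndarray:
        return np.asarray(self.n_correct) / np.asarray(self.n_presented)


@dataclass(frozen=True)
class PsychometricFit:
    mu: float
    sigma: float
    threshold: float
    guess_rate: float = 0.0
    converged: bool = True
    degenerate: bool = False
    nll: float = float("nan")


@dataclass(frozen=True)
class ConditionResult:
    """Acuity and precision for one amplitude x frequency x strategy cell."""

    condition: dict
    strategy: str
    acuity: float
    slope: float
    acuity_sem: float
    slope_sem: float
    mc_acuity_sd: float
    mc_slope_sd: float
    n_replicates: int
    replicate_acuities: tuple[float, ...] = ()
    replicate_slopes: tuple[float, ...] = ()


def initial_center(
    signal: DefocusSignal,
    levels: tuple[float, ...],
    cfg: SessionConfig,
    baseline_acuity: float = 0.0,
) -> float:
    """Starting center of the size window: the clinically expected acuity for
    the condition's effective defocus, clipped so all 11 sizes exist."""
    eff = abs(signal.dc_offset_d) + 0.5 * signal.amplitude_d
    center = baseline_acuity + cfg.center_slope_per_d * eff
    half = (cfg.n_sizes - 1) / 2 * cfg.size_step
    lo, hi = min(levels) + half, max(levels) - half
    return round(float(np.clip(round(center, 1), lo, hi)), 1)


def _size_window(center: float, cfg: SessionConfig) -> list[float]:
    half = (cfg.n_sizes - 1) // 2
    return [round(center + cfg.size_step * (i - half), 1) for i in range(cfg.n_sizes)]


def run_constant_stimuli(
    engine: AcuityEngine,
    signal: DefocusSignal,
    strategy: Strategy | str,
    rng: np.random.Generator,
    cfg: SessionConfig | None = None,
    condition: dict | None = None,
) -> PsychometricData:
    """Simulate one 110-trial constant-stimuli session.

    Letters, presentation order and epoch placement are all drawn from
    ``rng``, so a fixed seed reproduces the session bit for bit.
    """
    cfg = cfg or SessionConfig()
    levels = engine.bank.levels
    center = initial_center(signal, levels, cfg)
    strategy = Strategy(strategy)
    letters = engine.bank.letters

    for restart in range(cfg.max_restarts + 1):
        sizes = _size_window(center, cfg)
        if any(round(s, 1) not in {round(l, 1) for l in levels} for s in sizes):
            raise SessionError(f"size window {sizes[0]}..{sizes[-1]} leaves the bank")
        schedule = np.repeat(np.arange(cfg.n_sizes), cfg.reps_per_size)
        rng.shuffle(schedule)
        correct = np.zeros(cfg.n_sizes, dtype=int)
        presented = np.zeros(cfg.n_sizes, dtype=int)
        outcomes: list[bool] = []
        aborted = 0
        for k, si in enumerate(schedule):
            letter = letters[int(rng.integers(len(letters)))]
            out = engine.run_trial(letter, sizes[si], signal, strategy, rng)
            presented[si] += 1
            correct[si] += int(out.correct)
            outcomes.append(out.correct)
            if k + 1 == cfg.recenter_after:
                if all(outcomes):
                    aborted = -1  # ceiling: make the letters smaller
                    break
                if not any(outcomes):
                    aborted = +1  # floor: make the letters larger
                    break
        if not aborted:
            return PsychometricData(
                levels=tuple(sizes),
                n_correct=tuple(int(c) for c in correct),
                n_presented=tuple(int(p) for p in presented),
                condition=dict(condition or {}),
                restarts=restart,
            )
        new_center = round(center + aborted * cfg.recenter_step, 1)
        half = (cfg.n_sizes - 1) / 2 * cfg.size_step
        new_center = round(float(np.clip(new_center, min(levels) + half, max(levels) - half)), 1)
        if new_center == center:
            raise SessionError("recentering hit the edge of the optotype bank")
        center = new_center
    raise SessionError(f"no stable size window after {cfg.max_restarts} restarts")


# ---------------------------------------------------------------------------
# Psychometric fitting
# ---------------------------------------------------------------------------


def _nll(params: np.ndarray, s: np.ndarray, k: np.ndarray, n: np.ndarray, guess: float) -> float:
    mu, log_sigma = params
    sigma = math.exp(min(log_sigma, 3.0))
    p = guess + (1.0 - guess) * norm.cdf((s - mu) / sigma)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return float(-(k * np.log(p) + (n - k) * np.log(1.0 - p)).sum())


def fit_psychometric(data: PsychometricData, guess_rate: float = 0.0) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of proportion correct
    against logMAR size (probability of correct increases with size).

    ``guess_rate`` = 0 reproduces the free 0-to-1 fit; setting it to
    ``CHANCE_RATE_26AFC`` gives the optional guess-rate-corrected mode.
    Threshold is the size at 51.9% correct of the fitted function.
    """
    s = np.asarray(data.levels, dtype=float)
    k = np.asarray(data.n_correct, dtype=float)
    n = np.asarray(data.n_presented, dtype=float)
    p_hat = k / n

    degenerate = bool(p_hat.min() >= 0.999 or p_hat.max() <= 0.001)

    # crude threshold guess: first size whose running proportion passes 0.5
    order = np.argsort(s)
    above = order[p_hat[order] >= 0.5]
    mu0 = float(s[above[0]]) if above.size else float(s.max())
    starts = [(mu0, math.log(sig0)) for sig0 in (0.05, 0.1, 0.2, 0.4)]
    starts.append((float(s.mean()), math.log(0.15)))

    best = None
    for x0 in starts:
        res = minimize(
            _nll,
            np.asarray(x0),
            args=(s, k, n, guess_rate),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x
    sigma = math.exp(min(log_sigma, 3.0))
    crit = (THRESHOLD_CRITERION - guess_rate) / (1.0 - guess_rate)
    threshold = mu + sigma * norm.ppf(crit)
    return PsychometricFit(
        mu=float(mu),
        sigma=float(sigma),
        threshold=float(threshold),
        guess_rate=guess_rate,
        converged=bool(best.success) and not degenerate,
        degenerate=degenerate,
        nll=float(best.fun),
    )


def monte_carlo_variance(
    data: PsychometricData,
    fit: PsychometricFit,
    rng: np.random.Generator,
    n_rep: int = 100,
) -> tuple[float, float]:
    """Monte-Carlo (binomial-resampling) SDs of threshold and sigma.

    Per-size counts are redrawn as Binomial(n, p_hat) (variance
    p_hat (1 - p_hat) / n) and the psychometric function is refitted
    ``n_rep`` times; failed refits are dropped.
    """
    n = np.asarray(data.n_presented)
    p_hat = data.proportions()
    thresholds, sigmas = [], []
    for _ in range(n_rep):
        k = rng.binomial(n, p_hat)
        resampled = replace(data, n_correct=tuple(int(x) for x in k))
        try:
            f = fit_psychometric(resampled, guess_rate=fit.guess_rate)
        except Exception:
            continue
        thresholds.append(f.threshold)
        sigmas.append(f.sigma)
    if len(thresholds) < 2:
        return 0.0, 0.0
    return float(np.std(thresholds, ddof=1)), float(np.std(sigmas, ddof=1))


def regression_by_frequency(
    acuity_by_amplitude: dict[float, float],
) -> dict[str, float | None]:
    """OLS of mean acuity (logMAR) on defocus amplitude (D) at one frequency.

    Expects the four amplitude conditions (baseline excluded); returns slope
    (logMAR/D), intercept and R^2 (None when the acuities are constant).
    """
    if len(acuity_by_amplitude) < 2:
        raise ValueError("need at least two amplitude conditions")
    amps = np.asarray(sorted(acuity_by_amplitude), dtype=float)
    acu = np.asarray([acuity_by_amplitude[a] for a in amps], dtype=float)
    if np.allclose(acu, acu[0]):
        return {"slope": 0.0, "intercept": float(acu[0]), "r2": None}
    res = linregress(amps, acu)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
    }
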