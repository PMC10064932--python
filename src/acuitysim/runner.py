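"""Study orchestration: full grids, static-defocus validation, and the
residual-hyperopia offset experiment.

The temporal grid covers 4 amplitudes x 4 frequencies plus a no-defocus
baseline (17 conditions) for each decision strategy, mirroring the study
protocol.  Every condition x replicate gets an independent seed derived from
the master seed and a stable condition tag, so results do not depend on the
order in which conditions are run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AcuityEngine
from .psychophysics import (
    ConditionResult,
    SessionConfig,
    fit_psychometric,
    monte_carlo_variance,
    regression_by_frequency,
    run_constant_stimuli,
)
from .temporal import DefocusSignal, Strategy

__all__ = [
    "StudyConfig",
    "condition_rng",
    "run_condition",
    "run_grid",
    "run_static_series",
    "run_offset_experiment",
    "results_frame",
    "regression_table",
]

AMPLITUDES_D = (0.25, 0.5, 1.0, 2.0)
FREQUENCIES_HZ = (0.25, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class StudyConfig:
    amplitudes_d: tuple[float, ...] = AMPLITUDES_D
    frequencies_hz: tuple[float, ...] = FREQUENCIES_HZ
    strategies: tuple[str, ...] = tuple(s.value for s in Strategy)
    include_baseline: bool = True
    static_defocus_d: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    offset_d: float = 0.5
    offset_amplitude_d: float = 0.5
    offset_frequency_hz: float = 2.0
    master_seed: int = 0
    n_replicates: int = 10
    mc_reps: int = 100
    session: SessionConfig = field(default_factory=SessionConfig)


def condition_rng(master_seed: int, tag: str, replicate: int) -> np.random.Generator:
    """Reorder-invariant per-condition generator (crc32 of the tag)."""
    h = zlib.crc32(tag.encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h, int(replicate)])
    )


def _signal_tag(signal: DefocusSignal, strategy: str) -> str:
    return (
        f"A{signal.amplitude_d:g}:F{signal.frequency_hz:g}:"
        f"O{signal.dc_offset_d:g}:S{strategy}"
    )


def run_condition(
    engine: AcuityEngine,
    signal: DefocusSignal,
    strategy: Strategy | str,
    cfg: StudyConfig,
    condition_meta: dict | None = None,
) -> ConditionResult:
    """Run one condition over ``n_replicates`` seeded sessions.

    Reports the across-replicate mean and SEM of acuity and slope, plus the
    mean within-session Monte-Carlo SDs.
    """
    strategy = Strategy(strategy)
    tag = _signal_tag(signal, strategy.value)
    meta = {
        "amplitude_d": signal.amplitude_d,
        "frequency_hz": signal.frequency_hz,
        "offset_d": signal.dc_offset_d,
        **(condition_meta or {}),
    }
    acuities, slopes, mc_a, mc_s = [], [], [], []
    for rep in range(cfg.n_replicates):
        rng = condition_rng(cfg.master_seed, tag, rep)
        data = run_constant_stimuli(
            engine, signal, strategy, rng, cfg.session, condition=meta
        )
        fit = fit_psychometric(data)
        acuities.append(fit.threshold)
        slopes.append(fit.sigma)
        if cfg.mc_reps > 0:
            a_sd, s_sd = monte_carlo_variance(data, fit, rng, n_rep=cfg.mc_reps)
            mc_a.append(a_sd)
            mc_s.append(s_sd)
    n = len(acuities)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ConditionResult(
        condition=meta,
        strategy=strategy.value,
        acuity=float(np.mean(acuities)),
        slope=float(np.mean(slopes)),
        acuity_sem=sem(acuities),
        slope_sem=sem(slopes),
        mc_acuity_sd=float(np.mean(mc_a)) if mc_a else 0.0,
        mc_slope_sd=float(np.mean(mc_s)) if mc_s else 0.0,
        n_replicates=n,
        replicate_acuities=tuple(acuities),
        replicate_slopes=tuple(slopes),
    )


def _baseline_signal() -> DefocusSignal:
    # amplitude 0: the frequency is irrelevant but must be positive
    return DefocusSignal(amplitude_d=0.0, frequency_hz=1.0)


def run_grid(engine: AcuityEngine, cfg: StudyConfig | None = None) -> list[ConditionResult]:
    """Full temporal study: (baseline + amplitudes x frequencies) x strategies."""
    cfg = cfg or StudyConfig()
    results: list[ConditionResult] = []
    for strategy in cfg.strategies:
        if cfg.include_baseline:
            results.append(
                run_condition(
                    engine, _baseline_signal(), strategy, cfg, {"kind": "baseline"}
                )
            )
        for f in cfg.frequencies_hz:
            for a in cfg.amplitudes_d:
                sig = DefocusSignal(amplitude_d=a, frequency_hz=f)
                results.append(
                    run_condition(engine, sig, strategy, cfg, {"kind": "temporal"})
                )
    return results


def run_static_series(
    engine: AcuityEngine, cfg: StudyConfig | None = None, strategy: str = "average"
) -> list[ConditionResult]:
    """Static-defocus validation mode: constant defocus (A = 0, DC = D)."""
    cfg = cfg or StudyConfig()
    results = []
    for d in cfg.static_defocus_d:
        sig = DefocusSignal(amplitude_d=0.0, frequency_hz=1.0, dc_offset_d=d)
        results.append(run_condition(engine, sig, strategy, cfg, {"kind": "static"}))
    return results


def run_offset_experiment(
    engine: AcuityEngine, cfg: StudyConfig | None = None
) -> list[ConditionResult]:
    """Defocus fluctuation about a hyperopic baseline (plus references).

    Returns the five strategy results for offset + fluctuation, then the
    static-offset-only and no-defocus reference conditions.
    """
    cfg = cfg or StudyConfig()
    results = []
    sig = DefocusSignal(
        amplitude_d=cfg.offset_amplitude_d,
        frequency_hz=cfg.offset_frequency_hz,
        dc_offset_d=cfg.offset_d,
    )
    for strategy in cfg.strategies:
        results.append(run_condition(engine, sig, strategy, cfg, {"kind": "offset"}))
    static = DefocusSignal(amplitude_d=0.0, frequency_hz=1.0, dc_offset_d=cfg.offset_d)
    results.append(
        run_condition(engine, static, "average", cfg, {"kind": "static-reference"})
    )
    results.append(
        run_condition(
            engine, _baseline_signal(), "average", cfg, {"kind": "baseline-reference"}
        )
    )
    return results


def results_frame(results: list[ConditionResult]) -> pd.DataFrame:
    """Tidy results table (one row per condition x strategy)."""
    rows = []
    for r in results:
        rows.append(
            {
                "kind": r.condition.get("kind", ""),
                "strategy": r.strategy,
                "amplitude_d": r.condition["amplitude_d"],
                "frequency_hz": r.condition["frequency_hz"],
                "offset_d": r.condition["offset_d"],
                "acuity_logmar": r.acuity,
                "slope_logmar": r.slope,
                "acuity_sem": r.acuity_sem,
                "slope_sem": r.slope_sem,
                "mc_acuity_sd": r.mc_acuity_sd,
                "mc_slope_sd": r.mc_slope_sd,
                "n_replicates": r.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def regression_table(results: list[ConditionResult]) -> pd.DataFrame:
    """Per-strategy, per-frequency OLS of acuity on amplitude (4 points)."""
    df = results_frame(results)
    temporal = df[df["kind"] == "temporal"]
    rows = []
    for (strategy, f), grp in temporal.groupby(["strategy", "frequency_hz"]):
        fit = regression_by_frequency(
            dict(zip(grp["amplitude_d"], grp["acuity_logmar"]))
        )
        rows.append(
            {
                "strategy": strategy,
                "frequency_hz": f,
                "slope_logmar_per_d": fit["slope"],
                "intercept_logmar": fit["intercept"],
                "r2": fit["r2"],
            }
        )
    return pd.DataFrame(rows)
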