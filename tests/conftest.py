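"""Shared fixtures: one engine per test session, plus cached study blocks.

Simulation blocks (a strategy x frequency sweep over the four study
amplitudes) are expensive, so they are computed once and shared by the
acceptance and property tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

from acuitysim.model import AcuityEngine
from acuitysim.psychophysics import regression_by_frequency
from acuitysim.runner import StudyConfig, run_condition
from acuitysim.temporal import DefocusSignal

AMPS = (0.25, 0.5, 1.0, 2.0)


@pytest.fixture(scope="session")
def engine() -> AcuityEngine:
    return AcuityEngine()


class BlockCache:
    """Lazily computed amplitude sweeps keyed by (strategy, freq, reps)."""

    def __init__(self, engine: AcuityEngine):
        self.engine = engine
        self._blocks: dict = {}
        self._conditions: dict = {}

    def condition(self, signal: DefocusSignal, strategy: str, reps: int):
        key = (signal, strategy, reps)
        if key not in self._conditions:
            cfg = StudyConfig(master_seed=0, n_replicates=reps, mc_reps=0)
            self._conditions[key] = run_condition(self.engine, signal, strategy, cfg)
        return self._conditions[key]

    def amplitude_sweep(self, strategy: str, freq: float, reps: int):
        """Mean acuity per amplitude plus the acuity-on-amplitude OLS."""
        key = (strategy, freq, reps)
        if key not in self._blocks:
            acuity = {
                a: self.condition(DefocusSignal(a, freq), strategy, reps).acuity
                for a in AMPS
            }
            self._blocks[key] = {
                "acuity": acuity,
                "regression": regression_by_frequency(acuity),
            }
        return self._blocks[key]

    def baseline(self, reps: int = 10):
        return self.condition(DefocusSignal(0.0, 1.0), "average", reps)


@pytest.fixture(scope="session")
def blocks(engine) -> BlockCache:
    return BlockCache(engine)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
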