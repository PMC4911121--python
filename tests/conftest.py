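"""Shared fixtures; expensive calibrations are session-scoped."""

import numpy as np
import pytest

from sgsc.circuits import calibrate_gating_chain
from sgsc.meanfield import PulseSchedule


@pytest.fixture(scope="session")
def gating_cal():
    """Calibrated attractor gating-chain parameters (N2 = 100, ~3 ms)."""
    return calibrate_gating_chain(100, 0.003, seed=0)


@pytest.fixture(scope="session")
def fig1_bp(gating_cal):
    """The full 12-layer graded-transfer circuit (N1 = 1000)."""
    from sgsc.presets import build_fig1_sgsc

    return build_fig1_sgsc(seed=0, cal=gating_cal)


@pytest.fixture(scope="session")
def small_sgsc(gating_cal):
    """A cheaper 8-layer, N1 = 400 variant for unit-level checks."""
    from sgsc.presets import build_fig1_sgsc

    return build_fig1_sgsc(layers=8, N1=400, seed=0, cal=gating_cal)


@pytest.fixture(scope="session")
def sched_fig2():
    """The published overlapping-pulse schedule: T0/tau=0.6, T/tau=1.5."""
    return PulseSchedule.from_ratios(0.6, 2.5, tau=0.005)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
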