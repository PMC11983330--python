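"""Shared fixtures: calibrated shoulders and the simulated trial battery.

The trial battery (3-cycle 0-30 deg abduction-adduction, 0-3 kg handheld
loads, healthy / partial / full supraspinatus tear) is computed once per
session; individual tests read from it.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glenofdk as g
from glenofdk.fixtures import LoadCase, TearSpec, make_loadcases, make_motion
from glenofdk.solver import simulate_trial

settings.register_profile(
    "det", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("det")

SEED = 0


@pytest.fixture(scope="session")
def fixture0():
    """Default healthy synthetic shoulder, fully calibrated."""
    return g.default_fixture(seed=SEED)


@pytest.fixture(scope="session")
def study_profile():
    """The study protocol: three 0-30 deg cycles sampled at 5 Hz."""
    return make_motion(peak=30.0, n_cycles=3, frame_rate=5.0)


@pytest.fixture(scope="session")
def short_profile():
    """Single coarse cycle for cheap pipeline tests."""
    return make_motion(peak=30.0, n_cycles=1, frame_rate=2.5)


@pytest.fixture(scope="session")
def loadcases(fixture0):
    return make_loadcases(fixture0.anthropometrics)


@pytest.fixture(scope="session")
def trial_healthy_fdk(fixture0, study_profile, loadcases):
    return simulate_trial(fixture0, study_profile, loadcases[0], mode="fdk")


@pytest.fixture(scope="session")
def trial_healthy_default(fixture0, study_profile, loadcases):
    return simulate_trial(fixture0, study_profile, loadcases[0], mode="default")


@pytest.fixture(scope="session")
def tear_trials(study_profile, loadcases):
    """FDK trials for partial and full supraspinatus tears (0 kg)."""
    out = {}
    for label, tear in (("partial", TearSpec(supraspinatus=0.5)),
                        ("full", TearSpec(supraspinatus=0.0))):
        fx = g.default_fixture(seed=SEED, tear=tear)
        out[label] = (fx, simulate_trial(fx, study_profile, loadcases[0], mode="fdk"))
    return out


@pytest.fixture(scope="session")
def weight_trials(fixture0, study_profile, loadcases, trial_healthy_fdk):
    """Healthy FDK trials across the 0-3 kg handheld battery."""
    trials = {0.0: trial_healthy_fdk}
    for lc in loadcases[1:]:
        trials[lc.handheld_mass] = simulate_trial(fixture0, study_profile, lc, mode="fdk")
    return trials
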