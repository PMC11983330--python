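"""glenofdk: force-dependent-kinematics simulation of glenohumeral translation.

A desk-scale musculoskeletal shoulder model: the three GH translations are
solved per frame from quasi-static equilibrium of muscle, ligament,
elastic-foundation contact and external forces during scapular-plane
abduction-adduction with handheld loads, including rotator-cuff-tear variants
and a default spherical-joint comparison model.
"""

from .fixtures import (
    AnthropometricSpec,
    LoadCase,
    MotionProfile,
    ShoulderFixture,
    TearSpec,
    export_fixture,
    load_fixture,
    make_fixture,
    make_loadcases,
    make_motion,
    synth_fluoro_translations,
)
from .geometry import Frame, Pose, build_glenoid_frame, path_length_with_sphere_wrap
from .ligaments import LigamentBundle, calibrate_slack_lengths, ligament_tension
from .muscles import MuscleElement, apply_tear, calibrate_muscle_operating_range, strength_at
from .solver import (
    EquilibriumResult,
    FdkSettings,
    RecruitmentError,
    RecruitmentProblem,
    TrialResult,
    simulate_trial,
    solve_recruitment,
    translational_residual,
)
from .reporting import (
    compare_models,
    decompose_joint_reaction,
    export_results,
    summarize_translations,
    summarize_trial,
)

__version__ = "0.1.0"


def default_fixture(seed: int = 0, tear: TearSpec | None = None) -> ShoulderFixture:
    """Fully calibrated default synthetic shoulder (ligaments + muscle range)."""
    fx = make_fixture(tear=tear, seed=seed)
    fx = calibrate_muscle_operating_range(fx)
    return calibrate_slack_lengths(fx)
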