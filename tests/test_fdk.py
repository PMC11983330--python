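"""FDK outer loop: toy equilibria, escape flagging, residuals, determinism."""

import numpy as np
import pytest

from glenofdk.fixtures import LoadCase, make_loadcases, make_motion
from glenofdk.solver import (
    FdkSettings,
    RecruitmentProblem,
    fdk_solve_frame,
    simulate_trial,
    translational_residual,
)


def _cone():
    th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    a = np.deg2rad(35.0)
    rays = np.stack([np.sin(a) * np.cos(th), np.sin(a) * np.sin(th),
                     -np.cos(a) * np.ones(8)], axis=1)
    normals = np.cross(rays, np.roll(rays, -1, axis=0))
    flip = normals @ [0, 0, -1.0] < 0
    normals[flip] *= -1
    return normals


class _ToyAssembler:
    """Muscle-free world with a prescribed translational force field.

    ``field(u)`` returns the net passive force on the humerus; the
    recruitment stage sees zero torque demand and no actuators, so the FDK
    residual equals the field itself.
    """

    def __init__(self, field):
        self.field = field

    def assemble(self, elevation_deg, u):
        F = np.asarray(self.field(np.asarray(u, float)), dtype=float)
        problem = RecruitmentProblem(
            moment_arms=np.zeros((3, 0)), strengths=np.zeros(0),
            torque_demand=np.zeros(3), force_dirs=np.zeros((0, 3)),
            passive_force=-F, cone_normals=_cone())
        extras = {"F_lig": F, "F_grav": np.zeros(3), "F_contact": np.zeros(3),
                  "lig_tensions": np.zeros(0), "lig_strains": np.zeros(0),
                  "contact_volume": 0.0}
        return problem, extras


class TestOuterLoop:
    def test_linear_spring_equilibrium(self):
        # restoring stiffness 10 N/mm against a constant 20 N load -> u = 2 mm
        K = 10.0e3  # N/m
        load = np.array([20.0, 0.0, 0.0])
        toy = _ToyAssembler(lambda u: load - K * u)
        settings = FdkSettings(residual_threshold=0.01)
        res = fdk_solve_frame(None, toy, 0.0, 0.0, settings, u_init=np.zeros(3))
        assert res.converged
        assert res.u[0] == pytest.approx(2.0e-3, abs=1e-6)
        assert res.residual_norm < 0.01

    def test_anisotropic_spring_equilibrium(self):
        K = np.diag([5.0e3, 20.0e3, 50.0e3])
        load = np.array([10.0, -30.0, 80.0])
        toy = _ToyAssembler(lambda u: load - K @ u)
        res = fdk_solve_frame(None, toy, 0.0, 0.0, FdkSettings(residual_threshold=0.01),
                              u_init=np.zeros(3))
        assert res.converged
        assert np.allclose(res.u, np.linalg.solve(K, load), atol=1e-6)

    def test_superior_escape_flagged(self):
        # an unopposed superior force marches u to the bound
        toy = _ToyAssembler(lambda u: np.array([0.0, 50.0, 0.0]))
        res = fdk_solve_frame(None, toy, 0.0, 0.0, FdkSettings(max_outer_iterations=60),
                              u_init=np.zeros(3))
        assert not res.converged
        assert res.failure_mode == "superior_escape"
        assert res.u[1] >= 0.999 * FdkSettings().translation_bound

    def test_max_iterations_flagged(self):
        # the same unopposed force, but the budget runs out before the bound
        toy = _ToyAssembler(lambda u: np.array([0.0, 50.0, 0.0]))
        res = fdk_solve_frame(None, toy, 0.0, 0.0,
                              FdkSettings(max_outer_iterations=3),
                              u_init=np.zeros(3))
        assert not res.converged
        assert res.failure_mode == "max_iter"
        assert res.u[1] < FdkSettings().translation_bound


class TestTranslationalResidual:
    def test_handheld_mass_superposition(self, fixture0):
        """Adding 1 kg changes the residual by exactly (0, -9.81, 0) N."""
        lc0 = make_loadcases(fixture0.anthropometrics)[0]
        lc1 = LoadCase(handheld_mass=1.0, hand_offset=lc0.hand_offset)
        forces = np.zeros(fixture0.n_muscle_elements)
        u = np.array([0.0, 0.0, -0.0004])
        r0 = translational_residual(fixture0, lc0, 20.0, u, forces)
        r1 = translational_residual(fixture0, lc1, 20.0, u, forces)
        assert np.allclose(r1 - r0, [0.0, -9.81, 0.0], atol=1e-9)

    def test_residual_includes_contact_pushback(self, fixture0):
        lc0 = make_loadcases(fixture0.anthropometrics)[0]
        forces = np.zeros(fixture0.n_muscle_elements)
        free = translational_residual(fixture0, lc0, 0.0, [0, 0, 0.0], forces)
        pressed = translational_residual(fixture0, lc0, 0.0, [0, 0, -0.0012], forces)
        assert pressed[2] > free[2] + 10.0  # contact pushes laterally


class TestSimulateTrial:
    def test_deterministic_repeat(self, fixture0, loadcases):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=1.0)
        a = simulate_trial(fixture0, prof, loadcases[0], mode="fdk")
        b = simulate_trial(fixture0, prof, loadcases[0], mode="fdk")
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.u, fb.u)
            assert np.array_equal(fa.muscle_forces, fb.muscle_forces)
            assert fa.residual_norm == fb.residual_norm

    def test_default_mode_locks_translations(self, fixture0, loadcases):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=1.0)
        trial = simulate_trial(fixture0, prof, loadcases[0], mode="default")
        assert all(np.all(f.u == 0.0) for f in trial.frames)
        assert all(f.converged for f in trial.frames)
        assert all(np.all(f.contact_force == 0.0) for f in trial.frames)
        assert all(np.all(f.ligament_tensions == 0.0) for f in trial.frames)

    def test_unconverged_fraction_marks_failure(self, fixture0, loadcases):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=1.0)
        strict = FdkSettings(residual_threshold=1e-12, max_outer_iterations=2)
        trial = simulate_trial(fixture0, prof, loadcases[0], strict, mode="fdk")
        assert trial.n_unconverged > 0.2 * len(trial.frames)
        assert trial.failed

    def test_invalid_mode_rejected(self, fixture0, loadcases):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=1.0)
        with pytest.raises(ValueError):
            simulate_trial(fixture0, prof, loadcases[0], mode="both")
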