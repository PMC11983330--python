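"""Cubic-criterion recruitment against closed forms and brute-force grids."""

import numpy as np
import pytest

from glenofdk.solver import RecruitmentError, RecruitmentProblem, solve_recruitment


def _cone(axis=(0, 0, -1.0), half_angle_deg=35.0, n=8):
    """Planar-facet linearisation of a circular cone around ``axis``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    a = np.deg2rad(half_angle_deg)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rays = (np.cos(a) * axis + np.sin(a) * (np.cos(th)[:, None] * e1
                                            + np.sin(th)[:, None] * e2))
    normals = np.cross(rays, np.roll(rays, -1, axis=0))
    flip = normals @ axis < 0
    normals[flip] *= -1
    return normals / np.linalg.norm(normals, axis=1)[:, None]


def _problem(arms, strengths, demand, dirs=None, passive=(0, 0, 0)):
    arms = np.atleast_2d(np.asarray(arms, float))
    n = arms.shape[1]
    if dirs is None:
        dirs = np.tile([0.0, 0.0, -1.0], (n, 1))  # pull medially: cone-safe
    return RecruitmentProblem(
        moment_arms=arms, strengths=np.asarray(strengths, float),
        torque_demand=np.asarray(demand, float), force_dirs=np.asarray(dirs, float),
        passive_force=np.asarray(passive, float), cone_normals=_cone())


class TestClosedForms:
    def test_single_actuator_balance(self):
        # one muscle, 0.02 m arm, 2 Nm demand -> 100 N
        prob = _problem([[0.02], [0.0], [0.0]], [500.0], [2.0, 0, 0])
        sol = solve_recruitment(prob)
        assert sol.forces[0] == pytest.approx(100.0, rel=1e-6)

    def test_symmetric_muscles_share_equally(self):
        prob = _problem([[0.02, 0.02], [0, 0], [0, 0]], [300.0, 300.0], [2.0, 0, 0])
        sol = solve_recruitment(prob)
        assert sol.forces[0] == pytest.approx(sol.forces[1], rel=1e-6)

    def test_strength_weighting_closed_form(self):
        # N = (100, 200), equal unit arms, demand 300 N: the cubic criterion
        # gives f_i proportional to N_i^{3/2} -> (78.4, 221.6) N
        prob = _problem([[1.0, 1.0], [0, 0], [0, 0]], [100.0, 200.0], [300.0, 0, 0])
        sol = solve_recruitment(prob)
        assert sol.forces[0] == pytest.approx(78.36, abs=0.1)
        assert sol.forces[1] == pytest.approx(221.64, abs=0.1)
        ratio = sol.forces[1] / sol.forces[0]
        assert ratio == pytest.approx(2.0 ** 1.5, rel=1e-3)

    def test_zero_strength_element_excluded(self):
        prob = _problem([[0.02, 0.02], [0, 0], [0, 0]], [500.0, 0.0], [2.0, 0, 0])
        sol = solve_recruitment(prob)
        assert sol.forces[1] == 0.0
        assert sol.forces[0] == pytest.approx(100.0, rel=1e-6)


class TestBruteForceOracle:
    def test_two_muscle_grid(self):
        # one torque equation; eliminate f2 via the balance and grid f1
        a = np.array([0.03, 0.018])
        N = np.array([400.0, 250.0])
        tau = 6.0
        prob = _problem([a, [0, 0], [0, 0]], N, [tau, 0, 0])
        sol = solve_recruitment(prob)
        f1 = np.linspace(0.0, tau / a[0], 400_001)
        f2 = (tau - a[0] * f1) / a[1]
        ok = f2 >= 0.0
        obj = (f1[ok] / N[0]) ** 3 + (f2[ok] / N[1]) ** 3
        assert sol.objective <= obj.min() * 1.01
        assert sol.torque_residual < 1e-6

    def test_three_muscle_grid(self):
        a = np.array([0.025, 0.02, 0.01])
        N = np.array([300.0, 500.0, 200.0])
        tau = 5.0
        prob = _problem([a, [0, 0, 0], [0, 0, 0]], N, [tau, 0, 0])
        sol = solve_recruitment(prob)
        f1 = np.linspace(0, tau / a[0], 701)
        f2 = np.linspace(0, tau / a[1], 701)
        F1, F2 = np.meshgrid(f1, f2)
        F3 = (tau - a[0] * F1 - a[1] * F2) / a[2]
        ok = F3 >= 0.0
        obj = ((F1[ok] / N[0]) ** 3 + (F2[ok] / N[1]) ** 3 + (F3[ok] / N[2]) ** 3)
        assert sol.objective <= obj.min() * 1.01


class TestStabilityCone:
    def test_cone_forces_co_contraction(self):
        # a superiorly-pulling prime mover alone violates the cone; a medial
        # stabiliser must be recruited even though it adds no useful torque
        arms = np.array([[0.025, 0.0], [0.0, 0.0], [0.0, 0.0]])
        dirs = np.array([[0.0, 1.0, 0.0],   # pulls the humerus superiorly
                         [0.0, 0.0, -1.0]])  # compresses medially
        prob = RecruitmentProblem(
            moment_arms=arms, strengths=np.array([500.0, 500.0]),
            torque_demand=np.array([2.0, 0, 0]), force_dirs=dirs,
            passive_force=np.zeros(3), cone_normals=_cone())
        sol = solve_recruitment(prob)
        assert sol.forces[0] == pytest.approx(80.0, rel=1e-6)  # torque balance
        assert sol.forces[1] > 0.0  # stabiliser co-contracts
        v = -sol.joint_reaction
        assert np.all(prob.cone_normals @ v >= -1e-6)
        # reaction tilted no further than the cone half-angle off the axis
        angle = np.degrees(np.arccos((v / np.linalg.norm(v)) @ [0, 0, -1.0]))
        assert angle <= 35.0 + 1e-6

    def test_reaction_is_minus_sum_of_applied_forces(self):
        prob = _problem([[0.02, 0.02], [0, 0], [0, 0]], [400.0, 400.0],
                        [2.0, 0, 0], passive=(5.0, -30.0, 0.0))
        sol = solve_recruitment(prob)
        total = (sol.forces[:, None] * prob.force_dirs).sum(axis=0) + prob.passive_force
        assert np.allclose(sol.joint_reaction, -total, atol=1e-9)


class TestInfeasibility:
    def test_unreachable_torque_raises(self):
        # positive arms cannot produce a negative torque with f >= 0
        prob = _problem([[0.02], [0.0], [0.0]], [500.0], [-2.0, 0, 0])
        with pytest.raises(RecruitmentError):
            solve_recruitment(prob)

    def test_no_active_muscles_nonzero_demand_raises(self):
        prob = _problem([[0.02], [0.0], [0.0]], [0.0], [2.0, 0, 0])
        with pytest.raises(RecruitmentError):
            solve_recruitment(prob)

    def test_no_active_muscles_zero_demand_ok(self):
        prob = _problem([[0.02], [0.0], [0.0]], [0.0], [0.0, 0, 0],
                        passive=(0.0, 0.0, -10.0))
        sol = solve_recruitment(prob)
        assert np.allclose(sol.forces, 0.0)
        assert np.allclose(sol.joint_reaction, [0.0, 0.0, 10.0])
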