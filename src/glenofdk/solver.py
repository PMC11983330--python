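"""Muscle recruitment and the force-dependent-kinematics (FDK) outer loop.

Per frame, the primary kinematics (elevation in the scapular plane) are
prescribed and two nested problems are solved:

1. *Recruitment* (inner): distribute muscle-element forces to balance the
   three rotational DOFs of the GH joint, minimising the cubic polynomial
   criterion sum_i (f_i / N_i)^3 subject to moment balance, non-negativity
   and the glenoid stability cone - the required joint reaction must point
   through the glenoid cavity rim.  N_i is the instantaneous Hill strength
   of the element; elements with zero strength (torn muscles) are removed.
   Following the polynomial-criterion convention, N_i normalises the
   objective but does not hard-cap the force.

2. *FDK equilibrium* (outer): the three GH translations u are unconstrained
   and are found by a damped quasi-Newton iteration driving the net
   translational force on the humerus (muscles + ligaments + elastic-
   foundation contact + gravity) below the residual threshold (10 N).
   Inertial terms are neglected (quasi-static task).

The default spherical-joint model is the same recruitment with u locked at
zero and no ligament/contact contributions: the ideal joint supplies the
reaction directly, subject to the same stability cone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize

from .contact import contact_wrench
from .geometry import Pose, pose_transform, rotated_about, wrap_lengths
from .ligaments import bundle_strains, ligament_tension
from .muscles import force_length, normalized_length

log = logging.getLogger(__name__)

MOMENT_ARM_STEP_DEG = 0.25  # tendon-excursion central-difference step


class RecruitmentError(RuntimeError):
    """Raised when no muscle-force distribution satisfies the constraints."""

    def __init__(self, msg: str, violated: str | None = None):
        super().__init__(msg)
        self.violated = violated


@dataclass
class FdkSettings:
    residual_threshold: float = 10.0  # N
    max_outer_iterations: int = 60
    step_limit: float = 5.0e-4  # m per outer iteration
    translation_bound: float = 0.010  # m, box bound on u
    fd_step: float = 1.0e-5  # m, finite-difference step for the outer Jacobian
    jacobian_refresh: int = 10  # full FD refresh period (Broyden in between)

    def __post_init__(self):
        if self.residual_threshold <= 0:
            raise ValueError("residual_threshold must be > 0")


@dataclass
class RecruitmentProblem:
    """One frame's torque-balance + stability-cone optimisation instance."""

    moment_arms: np.ndarray  # (3, n) m/rad about the head centre axes
    strengths: np.ndarray  # (n,) instantaneous strengths N_i >= 0
    torque_demand: np.ndarray  # (3,) = -(external + ligament + contact torque)
    force_dirs: np.ndarray  # (n, 3) unit pull directions on the humerus
    passive_force: np.ndarray  # (3,) gravity + ligament force on the humerus
    cone_normals: np.ndarray  # (m, 3) inward facet normals, m >= 3

    def __post_init__(self):
        if np.any(self.strengths < 0):
            raise ValueError("strengths must be >= 0")
        if len(self.cone_normals) < 3:
            raise ValueError("stability cone needs >= 3 facets")


@dataclass
class RecruitmentSolution:
    forces: np.ndarray  # (n,) element forces, zeros for excluded elements
    joint_reaction: np.ndarray  # (3,) required reaction on the humerus
    objective: float
    torque_residual: float  # relative moment-balance violation


@dataclass
class EquilibriumResult:
    time: float
    elevation_deg: float
    u: np.ndarray
    muscle_forces: np.ndarray  # per element, N
    ligament_tensions: np.ndarray  # per spring, N
    ligament_strains: np.ndarray  # per spring
    contact_force: np.ndarray
    contact_volume: float
    joint_reaction: np.ndarray  # on the humerus, glenoid frame
    residual_norm: float
    torque_residual: float
    converged: bool
    failure_mode: str = "none"  # none | superior_escape | max_iter | recruitment_infeasible
    n_outer_iterations: int = 0


@dataclass
class TrialResult:
    mode: str  # "fdk" | "default"
    loadcase: "LoadCase"  # noqa: F821
    profile: "MotionProfile"  # noqa: F821
    tear_group: str
    frames: list[EquilibriumResult] = field(default_factory=list)
    failed: bool = False

    @property
    def n_unconverged(self) -> int:
        return sum(not f.converged for f in self.frames)

    @property
    def converged_frames(self) -> list[EquilibriumResult]:
        return [f for f in self.frames if f.converged]


# ---------------------------------------------------------------------------
# frame assembly
# ---------------------------------------------------------------------------

class _FrameAssembler:
    """Precomputed arrays + per-pose evaluation of all force contributions."""

    def __init__(self, fixture, loadcase, include_passive: bool = True):
        self.fixture = fixture
        self.loadcase = loadcase
        self.include_passive = include_passive
        self.m_origins = np.array([e.origin for e in fixture.muscles])
        self.m_ins_local = np.array([e.insertion_local for e in fixture.muscles])
        self.m_F0 = np.array([e.F0 for e in fixture.muscles])
        self.m_lopt = np.array([e.l_opt if e.l_opt is not None else np.nan
                                for e in fixture.muscles])
        self.m_lhalf = np.array([e.l_half if e.l_half is not None else np.nan
                                 for e in fixture.muscles])
        if np.any(np.isnan(self.m_lopt)) or np.any(np.isnan(self.m_lhalf)):
            raise RuntimeError("fixture muscles are not operating-range calibrated")
        self.m_tear = np.array([e.tear_factor for e in fixture.muscles])
        self.l_origins = np.vstack([b.origins for b in fixture.ligaments])
        self.l_ins_local = np.vstack([b.insertions_local for b in fixture.ligaments])
        self._bundle_slices = []
        k = 0
        for b in fixture.ligaments:
            self._bundle_slices.append((b, slice(k, k + b.n_springs)))
            k += b.n_springs
        self.cone = fixture.cone_normals()
        self.contacts = fixture.contact_models() if include_passive else []
        self.hand_local = np.asarray(loadcase.hand_offset, dtype=float)
        self._axes = np.eye(3)
        self._dstep = np.deg2rad(MOMENT_ARM_STEP_DEG)

    def _paths(self, ins_world_m, ins_world_l, center):
        """Lengths and pull directions for all muscle and ligament paths."""
        r = self.fixture.head_radius
        Lm, _, dm = wrap_lengths(self.m_origins, ins_world_m, center, r, return_dirs=True)
        Ll, _, dl = wrap_lengths(self.l_origins, ins_world_l, center, r, return_dirs=True)
        return Lm, dm, Ll, dl

    def assemble(self, elevation_deg: float, u: np.ndarray):
        fx = self.fixture
        lc = self.loadcase
        pose = Pose(elevation_deg=elevation_deg,
                    plane_offset_deg=0.0, axial_deg=0.0, u=u)
        T = pose_transform(pose, fx.head_center)
        hc = T.head_center
        ins_m = T.apply_local(self.m_ins_local)
        ins_l = T.apply_local(self.l_ins_local)
        Lm, dm, Ll, dl = self._paths(ins_m, ins_l, hc)

        # tendon-excursion moment arms about the head-centre axes
        n_m, n_l = len(Lm), len(Ll)
        ma_m = np.zeros((3, n_m))
        ma_l = np.zeros((3, n_l))
        for k in range(3):
            Lp = []
            for sign in (+1.0, -1.0):
                im = rotated_about(ins_m, self._axes[k], sign * self._dstep, hc)
                il = rotated_about(ins_l, self._axes[k], sign * self._dstep, hc)
                lm, _ = wrap_lengths(self.m_origins, im, hc, fx.head_radius)
                ll, _ = wrap_lengths(self.l_origins, il, hc, fx.head_radius)
                Lp.append((lm, ll))
            ma_m[k] = -(Lp[0][0] - Lp[1][0]) / (2.0 * self._dstep)
            ma_l[k] = -(Lp[0][1] - Lp[1][1]) / (2.0 * self._dstep)

        # instantaneous strengths (quasi-static: f_v = 1)
        l_norm = normalized_length(Lm, self.m_lopt, self.m_lhalf)
        strengths = self.m_tear * self.m_F0 * force_length(l_norm)

        # ligaments
        tensions = np.zeros(n_l)
        strains = np.zeros(n_l)
        if self.include_passive:
            for b, sl in self._bundle_slices:
                tensions[sl] = ligament_tension(b, Ll[sl])
                strains[sl] = bundle_strains(b, Ll[sl])
        F_lig = (tensions[:, None] * dl).sum(axis=0)
        tau_lig = ma_l @ tensions

        # gravity (arm + handheld)
        g = lc.gravity
        w_arm = np.array([0.0, -fx.arm.mass * g, 0.0])
        w_hand = np.array([0.0, -lc.handheld_mass * g, 0.0])
        p_com = T.apply_local(fx.arm.com_local)
        p_hand = T.apply_local(self.hand_local)
        F_grav = w_arm + w_hand
        tau_grav = np.cross(p_com - hc, w_arm) + np.cross(p_hand - hc, w_hand)

        # elastic-foundation contact (bone + labrum wrenches add)
        F_con = np.zeros(3)
        tau_con = np.zeros(3)
        vol = 0.0
        for model in self.contacts:
            patch = contact_wrench(model, T)
            F_con += patch.force
            tau_con += patch.moment - np.cross(hc, patch.force)  # shift to head centre
            vol += patch.penetration_volume

        problem = RecruitmentProblem(
            moment_arms=ma_m, strengths=strengths,
            torque_demand=-(tau_grav + tau_lig + tau_con),
            force_dirs=dm, passive_force=F_grav + F_lig,
            cone_normals=self.cone)
        extras = {"F_contact": F_con, "contact_volume": vol,
                  "lig_tensions": tensions, "lig_strains": strains,
                  "F_lig": F_lig, "F_grav": F_grav}
        return problem, extras


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def solve_recruitment(problem: RecruitmentProblem,
                      x0: np.ndarray | None = None) -> RecruitmentSolution:
    """Minimise the cubic recruitment criterion under torque balance and the
    stability cone.  Raises :class:`RecruitmentError` if infeasible."""
    N = problem.strengths
    active = N > 1e-9
    A = problem.moment_arms[:, active]
    D = problem.force_dirs[active]
    Na = N[active]
    b = problem.torque_demand
    n = int(active.sum())
    b_scale = 1.0 + np.linalg.norm(b)

    if n == 0:
        if np.linalg.norm(b) < 1e-9:
            return RecruitmentSolution(np.zeros(len(N)), -problem.passive_force, 0.0, 0.0)
        raise RecruitmentError("no active muscle elements but nonzero torque demand",
                               violated="moment_balance")

    G = problem.cone_normals @ D.T  # (m, n)
    h = problem.cone_normals @ problem.passive_force  # (m,)

    # drop degenerate moment-balance rows (no actuator authority about that
    # axis): 0 = 0 rows would make the SLSQP subproblem singular, and an
    # unreachable nonzero demand is infeasible outright
    row_scale = np.abs(A).max(axis=1, initial=0.0)
    trivial = row_scale < 1e-12
    if np.any(trivial & (np.abs(b) > 1e-9)):
        raise RecruitmentError(
            "torque demand about an axis with no muscle authority",
            violated="moment_balance")
    if np.any(trivial):
        A = A[~trivial]
        b = b[~trivial]

    # solve in activation-like variables x = f / N for conditioning
    As = A * Na
    Gs = G * Na

    def obj(x):
        return float(np.sum(x**3))

    def grad(x):
        return 3.0 * x**2

    cons = [
        {"type": "eq", "fun": lambda x: As @ x - b, "jac": lambda x: As},
        {"type": "ineq", "fun": lambda x: Gs @ x + h, "jac": lambda x: Gs},
    ]
    bounds = [(0.0, None)] * n

    def _attempt(start):
        return minimize(obj, start, jac=grad, bounds=bounds, constraints=cons,
                        method="SLSQP", options={"maxiter": 200, "ftol": 1e-10})

    def _violations(x):
        eq = np.linalg.norm(As @ x - b) / b_scale
        ineq = float(np.clip(-(Gs @ x + h), 0.0, None).max(initial=0.0))
        return eq, ineq

    ineq_scale = 1e-6 * (1.0 + np.abs(h).max(initial=0.0))
    starts = []
    if x0 is not None and len(x0) == len(N):
        starts.append(np.clip(x0[active] / Na, 0.0, None) + 1e-8)
    starts.append(np.full(n, 0.05))
    starts.append(np.clip(np.linalg.lstsq(As, b, rcond=None)[0], 0.0, None) + 1e-3)

    best = None
    for start in starts:
        res = _attempt(start)
        eq_viol, ineq_viol = _violations(res.x)
        if eq_viol < 1e-6 and ineq_viol < ineq_scale:
            best = (res, eq_viol)
            break
    if best is None:
        # feasibility certificate via LP before blaming the optimiser
        lp = linprog(np.zeros(n), A_eq=As, b_eq=b,
                     A_ub=-Gs, b_ub=h, bounds=[(0, None)] * n, method="highs")
        if not lp.success:
            raise RecruitmentError(
                "recruitment infeasible: no non-negative muscle forces satisfy "
                "moment balance and the stability cone", violated="stability_cone")
        res = _attempt(lp.x + 1e-3)
        eq_viol, _ = _violations(res.x)
        if eq_viol > 1e-5:
            raise RecruitmentError("recruitment optimiser failed to converge",
                                   violated="moment_balance")
        best = (res, eq_viol)

    res, eq_viol = best
    x = np.clip(res.x, 0.0, None)
    f_full = np.zeros(len(N))
    f_full[active] = x * Na
    reaction = -(D.T @ (x * Na) + problem.passive_force)
    return RecruitmentSolution(forces=f_full, joint_reaction=reaction,
                               objective=float(res.fun), torque_residual=float(eq_viol))


def translational_residual(fixture, loadcase, elevation_deg: float, u: np.ndarray,
                           forces: np.ndarray, include_passive: bool = True) -> np.ndarray:
    """Net translational force on the humerus (N) in the glenoid frame.

    Sums the muscle path forces (given per-element magnitudes), ligament
    tensions, elastic-foundation contact and gravity of arm plus handheld
    mass at the pose; inertial terms are omitted (quasi-static).
    """
    assembler = _FrameAssembler(fixture, loadcase, include_passive=include_passive)
    problem, extras = assembler.assemble(elevation_deg, np.asarray(u, dtype=float))
    F_musc = (np.asarray(forces, dtype=float)[:, None] * problem.force_dirs).sum(axis=0)
    return F_musc + extras["F_lig"] + extras["F_grav"] + extras["F_contact"]


# ---------------------------------------------------------------------------
# FDK outer loop
# ---------------------------------------------------------------------------

def _residual_at(assembler: _FrameAssembler, elevation_deg: float, u: np.ndarray,
                 x0: np.ndarray | None):
    problem, extras = assembler.assemble(elevation_deg, u)
    sol = solve_recruitment(problem, x0=x0)
    F_musc = (sol.forces[:, None] * problem.force_dirs).sum(axis=0)
    residual = F_musc + extras["F_lig"] + extras["F_grav"] + extras["F_contact"]
    return residual, sol, extras


def fdk_solve_frame(fixture, assembler: _FrameAssembler, time: float,
                    elevation_deg: float, settings: FdkSettings,
                    u_init: np.ndarray, x0: np.ndarray | None = None) -> EquilibriumResult:
    """Damped quasi-Newton iteration on the GH translations for one frame."""
    bound = settings.translation_bound
    u = np.clip(np.asarray(u_init, dtype=float), -bound, bound)
    r, sol, extras = _residual_at(assembler, elevation_deg, u, x0)

    def fd_jacobian(u0, r0, forces):
        # muscle recruitment varies slowly with u; freeze the forces and let
        # the Jacobian capture the stiff contact/ligament response (Broyden
        # updates pick up the recruitment coupling between refreshes)
        problem0, extras0 = assembler.assemble(elevation_deg, u0)
        F_musc0 = (forces[:, None] * problem0.force_dirs).sum(axis=0)
        r_frozen0 = F_musc0 + extras0["F_lig"] + extras0["F_grav"] + extras0["F_contact"]
        J = np.zeros((3, 3))
        for k in range(3):
            du = np.zeros(3)
            du[k] = settings.fd_step
            problem_k, extras_k = assembler.assemble(elevation_deg, u0 + du)
            F_musc = (forces[:, None] * problem_k.force_dirs).sum(axis=0)
            rk = F_musc + extras_k["F_lig"] + extras_k["F_grav"] + extras_k["F_contact"]
            J[:, k] = (rk - r_frozen0) / settings.fd_step
        return J

    J = None
    converged = False
    failure = "max_iter"
    it = 0
    for it in range(1, settings.max_outer_iterations + 1):
        if np.linalg.norm(r) < settings.residual_threshold:
            converged = True
            failure = "none"
            break
        if u[1] >= bound * 0.999:
            failure = "superior_escape"
            break
        if J is None or (it % settings.jacobian_refresh == 0):
            J = fd_jacobian(u, r, sol.forces)
        try:
            du = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            du = -np.linalg.pinv(J) @ r
        ndu = np.linalg.norm(du)
        if not np.isfinite(ndu) or ndu < 1e-12:
            # singular Jacobian (no restoring stiffness along the residual):
            # drift along the net force, as an unconstrained head would
            du = settings.step_limit * r / np.linalg.norm(r)
            ndu = settings.step_limit
        if ndu > settings.step_limit:
            du *= settings.step_limit / ndu
        # backtracking: accept the best candidate of up to 4 halvings
        best = None
        for _ in range(4):
            u_new = np.clip(u + du, -bound, bound)
            r_new, sol_new, extras_new = _residual_at(assembler, elevation_deg, u_new,
                                                      sol.forces)
            if best is None or np.linalg.norm(r_new) < np.linalg.norm(best[1]):
                best = (u_new, r_new, sol_new, extras_new)
            if np.linalg.norm(r_new) < np.linalg.norm(r):
                break
            du *= 0.5
        u_new, r_new, sol_new, extras_new = best
        s = u_new - u
        y = r_new - r
        if s @ s > 1e-24:  # Broyden rank-1 update
            J = J + np.outer(y - J @ s, s) / (s @ s)
        u, r, sol, extras = u_new, r_new, sol_new, extras_new
    else:
        it = settings.max_outer_iterations
    if converged:
        failure = "none"

    return EquilibriumResult(
        time=time, elevation_deg=elevation_deg, u=u.copy(),
        muscle_forces=sol.forces, ligament_tensions=extras["lig_tensions"],
        ligament_strains=extras["lig_strains"], contact_force=extras["F_contact"],
        contact_volume=extras["contact_volume"], joint_reaction=sol.joint_reaction,
        residual_norm=float(np.linalg.norm(r)), torque_residual=sol.torque_residual,
        converged=converged, failure_mode=failure, n_outer_iterations=it)


def simulate_trial(fixture, profile, loadcase, settings: FdkSettings | None = None,
                   mode: str = "fdk") -> TrialResult:
    """Run one abduction-adduction trial, frame by frame with warm starts.

    ``mode="fdk"`` solves the translational equilibrium per frame;
    ``mode="default"`` locks u at zero (ideal spherical joint, stability cone
    only, no ligaments or contact).  A trial with more than 20 % unconverged
    frames is marked failed; partial results are retained.
    """
    if mode not in ("fdk", "default"):
        raise ValueError("mode must be 'fdk' or 'default'")
    settings = settings or FdkSettings()
    assembler = _FrameAssembler(fixture, loadcase, include_passive=(mode == "fdk"))
    trial = TrialResult(mode=mode, loadcase=loadcase, profile=profile,
                        tear_group=fixture.tear.group)
    u = np.zeros(3)
    x_warm = None
    for t, elev in profile.frames:
        try:
            if mode == "default":
                problem, extras = assembler.assemble(elev, np.zeros(3))
                sol = solve_recruitment(problem, x0=x_warm)
                frame = EquilibriumResult(
                    time=t, elevation_deg=elev, u=np.zeros(3),
                    muscle_forces=sol.forces,
                    ligament_tensions=extras["lig_tensions"],
                    ligament_strains=extras["lig_strains"],
                    contact_force=np.zeros(3), contact_volume=0.0,
                    joint_reaction=sol.joint_reaction, residual_norm=0.0,
                    torque_residual=sol.torque_residual, converged=True)
            else:
                frame = fdk_solve_frame(fixture, assembler, t, elev, settings,
                                        u_init=u, x0=x_warm)
                u = frame.u
            x_warm = frame.muscle_forces
        except RecruitmentError as err:
            log.warning("frame t=%.3f: %s", t, err)
            frame = EquilibriumResult(
                time=t, elevation_deg=elev, u=u.copy(),
                muscle_forces=np.zeros(len(fixture.muscles)),
                ligament_tensions=np.zeros(len(assembler.l_origins)),
                ligament_strains=np.zeros(len(assembler.l_origins)),
                contact_force=np.zeros(3), contact_volume=0.0,
                joint_reaction=np.zeros(3), residual_norm=np.inf,
                torque_residual=np.inf, converged=False,
                failure_mode="recruitment_infeasible")
        trial.frames.append(frame)
    n = len(trial.frames)
    if n and trial.n_unconverged / n > 0.20:
        trial.failed = True
        log.warning("trial failed: %d/%d frames unconverged", trial.n_unconverged, n)
    return trial
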