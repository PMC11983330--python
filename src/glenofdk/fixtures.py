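"""Synthetic shoulder fixtures: geometry, actuators, ligaments, motion, loads.

Everything the simulation pipeline consumes is generated here, so a complete
trial runs with no external data.  The default construction emulates the
study conditions: near-congruent spherical articular surfaces (27 mm glenoid
cap, 25 mm humeral head) with a compliant labrum rim band that deepens the
socket, a 16-muscle / 118-element actuator roster, the four ligament systems
discretised into 2 + 2 + 8 + 5 springs, three 0-30 deg abduction-adduction
cycles in the scapular plane, handheld loads of 0-3 kg, and fluoroscopy-like
"measured" translation series (smaller amplitude than simulated ones, plus
measurement noise).

All generators are pure functions of their arguments and a seed.  The seed
perturbs soft-tissue attachment sites by ~1 mm to emulate between-subject
variability; the articular geometry itself is deterministic given the
anthropometrics.

Coordinates are metres in the glenoid frame (x anterior, y superior,
z lateral toward the humerus); the attachment tables are authored for a
1.75 m / 75 kg reference subject and scaled by height (lengths) and body
mass (strengths, 55 N/cm^2 specific tension on published PCSA fractions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .contact import BONE_PRESSURE_MODULE, LABRUM_PRESSURE_MODULE, ContactModel
from .geometry import Frame, build_glenoid_frame
from .ligaments import LigamentBundle
from .muscles import ROTATOR_CUFF, MuscleElement

REF_HEIGHT = 1.75  # m, reference stature of the attachment tables
REF_MASS = 75.0  # kg
SPECIFIC_TENSION = 55.0  # N/cm^2 applied to PCSA
ARM_LENGTH_FRACTION = 0.40  # GH centre to hand, extended arm, fraction of height
ARM_MASS_FRACTION = 0.05  # single rigid arm segment (upper arm + extended forearm/hand)
ARM_COM_FRACTION = 0.45  # COM position along the arm from the GH centre
SCAPULAR_PLANE_OFFSET_DEG = 30.0  # anterior of the coronal plane
DEFAULT_INITIAL_GAP = 5.0e-4  # m, articular clearance at the deepest glenoid point


class FixtureValidationError(ValueError):
    pass


def _require(cond: bool, fieldname: str, msg: str):
    if not cond:
        raise FixtureValidationError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class AnthropometricSpec:
    body_height: float = REF_HEIGHT  # m
    body_mass: float = REF_MASS  # kg
    humeral_head_radius: float = 0.025  # m
    glenoid_radius: float = 0.027  # m
    glenoid_cap_half_angle: float = 35.0  # deg
    labrum_rim_height: float = 0.004  # m

    def __post_init__(self):
        _require(self.body_height > 0, "body_height", "must be > 0")
        _require(self.body_mass > 0, "body_mass", "must be > 0")
        _require(self.humeral_head_radius > 0, "humeral_head_radius", "must be > 0")
        _require(self.glenoid_radius > 0, "glenoid_radius", "must be > 0")
        _require(self.glenoid_radius >= self.humeral_head_radius,
                 "glenoid_radius", "must be >= humeral_head_radius")
        _require(0 < self.glenoid_cap_half_angle < 90,
                 "glenoid_cap_half_angle", "must be in (0, 90) deg")
        _require(self.labrum_rim_height > 0, "labrum_rim_height", "must be > 0")


_TEAR_LEVELS = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class TearSpec:
    """Per-muscle strength factors for the four rotator-cuff muscles."""

    supraspinatus: float = 1.0
    infraspinatus: float = 1.0
    subscapularis: float = 1.0
    teres_minor: float = 1.0

    def __post_init__(self):
        for name in ROTATOR_CUFF:
            _require(getattr(self, name) in _TEAR_LEVELS, name, "must be 0, 0.5 or 1")

    @property
    def factors(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ROTATOR_CUFF}

    @property
    def group(self) -> str:
        vals = list(self.factors.values())
        if any(v == 0.0 for v in vals):
            return "full"
        if any(v == 0.5 for v in vals):
            return "partial"
        return "healthy"


@dataclass(frozen=True)
class MotionProfile:
    """Sampled elevation profile: repeated smooth 0 -> peak -> 0 cycles."""

    frames: tuple  # ((time s, elevation deg), ...)
    n_cycles: int
    peak_angle: float
    cycle_duration: float
    scapular_plane_offset: float = SCAPULAR_PLANE_OFFSET_DEG

    def elevation_at(self, t: float) -> float:
        span = self.n_cycles * self.cycle_duration
        if not (-1e-9 <= t <= span + 1e-9):
            raise ValueError(f"t={t} outside profile span [0, {span}]")
        phase = np.clip(t, 0.0, span) % self.cycle_duration
        return float(self.peak_angle * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / self.cycle_duration)))

    @property
    def times(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames])

    @property
    def elevations(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames])


@dataclass(frozen=True)
class LoadCase:
    handheld_mass: float  # kg
    gravity: float = 9.81  # m/s^2
    hand_offset: tuple = (0.0, -ARM_LENGTH_FRACTION * REF_HEIGHT, 0.0)  # humerus frame, m

    def __post_init__(self):
        _require(self.handheld_mass >= 0, "handheld_mass", "must be >= 0")
        _require(self.gravity > 0, "gravity", "must be > 0")


@dataclass
class ArmSegment:
    mass: float  # kg
    com_local: np.ndarray  # humerus frame, from head centre
    length: float  # GH centre to hand, m
    inertia: np.ndarray  # about COM, kg m^2 (unused in quasi-static trials)


@dataclass
class ShoulderFixture:
    """Complete synthetic shoulder model (glenoid frame coordinates)."""

    anthropometrics: AnthropometricSpec
    tear: TearSpec
    seed: int
    glenoid_mesh: trimesh.Trimesh
    labrum_mesh: trimesh.Trimesh
    humeral_head_mesh: trimesh.Trimesh
    glenoid_frame: Frame
    head_center: np.ndarray  # nominal (neutral pose) humeral head centre
    head_radius: float
    initial_gap: float
    muscles: list[MuscleElement]
    ligaments: list[LigamentBundle]
    arm: ArmSegment
    cone_rim_points: np.ndarray  # glenoid rim points defining the stability cone
    _contact: list[ContactModel] | None = field(default=None, repr=False)

    # -- derived collections -------------------------------------------------
    @property
    def muscle_names(self) -> list[str]:
        seen: list[str] = []
        for e in self.muscles:
            if e.muscle not in seen:
                seen.append(e.muscle)
        return seen

    @property
    def n_muscle_elements(self) -> int:
        return len(self.muscles)

    @property
    def ligament_spring_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.ligaments:
            counts[b.parent] = counts.get(b.parent, 0) + b.n_springs
        return counts

    def with_muscles(self, muscles, tear: TearSpec | None = None) -> "ShoulderFixture":
        return replace(self, muscles=list(muscles), tear=tear or self.tear, _contact=None)

    def with_ligaments(self, ligaments) -> "ShoulderFixture":
        return replace(self, ligaments=list(ligaments), _contact=None)

    def contact_models(self) -> list[ContactModel]:
        """Bone-on-bone and head-on-labrum elastic foundation models (cached)."""
        if self._contact is None:
            self._contact = [
                ContactModel(BONE_PRESSURE_MODULE, self.glenoid_mesh, self.humeral_head_mesh),
                ContactModel(LABRUM_PRESSURE_MODULE, self.labrum_mesh, self.humeral_head_mesh),
            ]
        return self._contact

    def cone_normals(self) -> np.ndarray:
        """Inward facet normals of the stability cone linearised through the rim.

        The cone apex is the nominal head centre; its rays run to the glenoid
        rim points, so the joint reaction on the glenoid is constrained to
        pass within the cavity.
        """
        rays = self.cone_rim_points - self.head_center
        rays = rays / np.linalg.norm(rays, axis=1)[:, None]
        axis = rays.mean(axis=0)
        axis /= np.linalg.norm(axis)
        n = len(rays)
        normals = np.cross(rays, rays[(np.arange(n) + 1) % n])
        flip = normals @ axis < 0
        normals[flip] *= -1
        return normals / np.linalg.norm(normals, axis=1)[:, None]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for arr in (self.glenoid_mesh.vertices, self.glenoid_mesh.faces,
                    self.labrum_mesh.vertices, self.humeral_head_mesh.vertices,
                    self.head_center, self.cone_rim_points):
            h.update(np.ascontiguousarray(arr).tobytes())
        for e in self.muscles:
            h.update(e.muscle.encode())
            h.update(np.ascontiguousarray(e.origin).tobytes())
            h.update(np.ascontiguousarray(e.insertion_local).tobytes())
            h.update(np.float64(e.F0).tobytes())
            h.update(np.float64(e.l_opt if e.l_opt is not None else -1.0).tobytes())
            h.update(np.float64(e.l_half if e.l_half is not None else -1.0).tobytes())
            h.update(np.float64(e.tear_factor).tobytes())
        for b in self.ligaments:
            h.update(b.name.encode())
            h.update(np.ascontiguousarray(b.origins).tobytes())
            h.update(np.ascontiguousarray(b.insertions_local).tobytes())
            h.update(np.float64(b.stiffness).tobytes())
            if b.slack_lengths is not None:
                h.update(np.ascontiguousarray(b.slack_lengths).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# attachment tables (reference subject 1.75 m / 75 kg)
# ---------------------------------------------------------------------------
# ("head", direction) insertions are placed on the humeral head at 1.06 x the
# head radius along the given direction from the centre (cuff/capsular
# footprints); plain tuples are humerus-frame points relative to the centre.

_MUSCLE_TABLE = [
    # name, n_elem, PCSA cm^2, origin span (a, b), insertion span (a, b)
    ("deltoid_anterior", 12, 8.0,
     (0.030, 0.028, 0.004), (0.012, 0.033, 0.016),
     (0.007, -0.100, 0.010), (0.004, -0.115, 0.013)),
    ("deltoid_lateral", 12, 9.0,
     (0.012, 0.038, 0.018), (-0.012, 0.038, 0.018),
     (0.002, -0.100, 0.015), (-0.002, -0.118, 0.014)),
    ("deltoid_posterior", 12, 8.0,
     (-0.030, 0.030, 0.002), (-0.014, 0.035, 0.014),
     (-0.006, -0.098, 0.011), (-0.003, -0.112, 0.013)),
    ("supraspinatus", 6, 6.0,
     (-0.052, 0.012, -0.022), (-0.030, 0.015, -0.012),
     ("head", (0.10, 0.72, 0.68)), ("head", (0.28, 0.60, 0.75))),
    ("infraspinatus", 12, 9.5,
     (-0.055, -0.010, -0.022), (-0.040, 0.002, -0.018),
     ("head", (-0.35, 0.55, 0.76)), ("head", (-0.55, 0.30, 0.78))),
    ("subscapularis", 12, 13.0,
     (-0.050, -0.005, -0.028), (-0.035, 0.004, -0.022),
     ("head", (0.80, 0.20, 0.56)), ("head", (0.78, -0.10, 0.62))),
    ("teres_minor", 6, 3.0,
     (-0.042, -0.035, -0.016), (-0.038, -0.025, -0.014),
     ("head", (-0.62, -0.10, 0.78)), ("head", (-0.55, -0.25, 0.79))),
    ("teres_major", 6, 8.0,
     (-0.045, -0.080, -0.022), (-0.040, -0.070, -0.018),
     (0.004, -0.050, -0.006), (0.006, -0.060, -0.004)),
    ("pectoralis_major_clavicular", 5, 5.0,
     (0.055, 0.022, -0.035), (0.035, 0.028, -0.012),
     (0.010, -0.045, 0.004), (0.009, -0.055, 0.004)),
    ("pectoralis_major_sternal", 5, 6.5,
     (0.065, -0.015, -0.060), (0.060, 0.000, -0.050),
     (0.010, -0.048, 0.002), (0.009, -0.058, 0.002)),
    ("pectoralis_major_abdominal", 5, 4.0,
     (0.060, -0.060, -0.060), (0.058, -0.045, -0.055),
     (0.009, -0.050, 0.000), (0.008, -0.058, 0.000)),
    ("latissimus_dorsi", 12, 8.5,
     (-0.055, -0.095, -0.045), (-0.045, -0.075, -0.040),
     (0.007, -0.048, -0.004), (0.006, -0.056, -0.002)),
    ("coracobrachialis", 3, 2.5,
     (0.024, 0.012, -0.008), (0.026, 0.010, -0.006),
     (0.003, -0.125, -0.008), (0.003, -0.135, -0.007)),
    ("biceps_long", 2, 3.0,
     (0.002, 0.016, -0.004), (0.003, 0.015, -0.003),
     (0.010, -0.295, 0.004), (0.010, -0.305, 0.004)),
    ("biceps_short", 2, 2.0,
     (0.026, 0.011, -0.007), (0.028, 0.009, -0.005),
     (0.010, -0.295, 0.002), (0.010, -0.305, 0.002)),
    ("triceps_long", 6, 6.7,
     (-0.002, -0.018, -0.004), (-0.006, -0.017, -0.003),
     (-0.012, -0.295, 0.000), (-0.012, -0.305, 0.000)),
]

_LIGAMENT_TABLE = [
    # name, parent, n_springs, stiffness N/-, (cal abd deg, cal axial deg), strain,
    # origin span, insertion directions on the head
    ("superior_gh", "superior_gh", 2, 550.0, (0.0, 20.0), 0.09,
     (0.009, 0.0145, -0.003), (0.005, 0.016, -0.003),
     (0.55, 0.35, 0.76), (0.62, 0.28, 0.73)),
    ("middle_gh", "middle_gh", 2, 375.0, (0.0, 0.0), 0.07,
     (0.016, 0.004, -0.003), (0.016, -0.002, -0.003),
     (0.80, 0.05, 0.60), (0.80, -0.05, 0.60)),
    ("inferior_gh_anterior", "inferior_gh", 3, 582.0, (60.0, 50.0), 0.11,
     (0.0135, -0.010, -0.003), (0.009, -0.0145, -0.003),
     (0.60, -0.50, 0.62), (0.45, -0.60, 0.66)),
    ("inferior_gh_posterior", "inferior_gh", 2, 320.0, (60.0, 30.0), 0.10,
     (-0.009, -0.0145, -0.003), (-0.0135, -0.010, -0.003),
     (-0.28, -0.87, 0.40), (-0.38, -0.80, 0.46)),
    ("inferior_gh_inferior", "inferior_gh", 3, 388.0, (60.0, -80.0), 0.10,
     (0.0035, -0.017, -0.003), (-0.0035, -0.017, -0.003),
     (0.04, -0.90, 0.44), (-0.04, -0.90, 0.44)),
    ("coracohumeral", "coracohumeral", 5, 1099.0, (0.0, 0.0), 0.05,
     (0.021, 0.014, -0.006), (0.027, 0.010, -0.010),
     (0.30, 0.45, 0.84), (0.60, 0.30, 0.74)),
]

HEAD_FOOTPRINT_FACTOR = 1.06  # attachment radius / head radius for head insertions
N_CONE_RIM_POINTS = 8


def _spherical_cap(radius: float, center: np.ndarray, phi0: float, phi1: float,
                   n_rings: int, n_sectors: int) -> trimesh.Trimesh:
    """Triangulated band of a sphere between polar angles phi0..phi1 around -z.

    Face normals are oriented toward the sphere centre (the cavity side that
    faces the humeral head).
    """
    phis = np.linspace(phi0, phi1, n_rings + 1)
    lams = np.linspace(0.0, 2.0 * np.pi, n_sectors, endpoint=False)
    verts = []
    pole = phi0 < 1e-12
    if pole:
        verts.append(center + radius * np.array([0.0, 0.0, -1.0]))
        phis = phis[1:]
    ring_start = len(verts)
    for phi in phis:
        for lam in lams:
            verts.append(center + radius * np.array(
                [np.sin(phi) * np.cos(lam), np.sin(phi) * np.sin(lam), -np.cos(phi)]))
    verts = np.array(verts)
    faces = []
    n_rings_eff = len(phis)
    if pole:
        for j in range(n_sectors):
            a = ring_start + j
            b = ring_start + (j + 1) % n_sectors
            faces.append([0, a, b])
    for i in range(n_rings_eff - 1):
        r0 = ring_start + i * n_sectors
        r1 = r0 + n_sectors
        for j in range(n_sectors):
            jn = (j + 1) % n_sectors
            faces.append([r0 + j, r1 + j, r1 + jn])
            faces.append([r0 + j, r1 + jn, r0 + jn])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    # orient normals toward the sphere centre (the side facing the head)
    toward = center - mesh.triangles.mean(axis=1)
    if np.mean(np.einsum("ij,ij->i", mesh.face_normals, toward)) < 0:
        mesh.invert()
    return mesh


def _resolve_insertion(entry, head_radius: float) -> np.ndarray:
    if isinstance(entry, tuple) and len(entry) == 2 and entry[0] == "head":
        d = np.asarray(entry[1], dtype=float)
        return HEAD_FOOTPRINT_FACTOR * head_radius * d / np.linalg.norm(d)
    return np.asarray(entry, dtype=float)


def make_fixture(spec: AnthropometricSpec | None = None,
                 tear: TearSpec | None = None,
                 seed: int = 0,
                 initial_gap: float = DEFAULT_INITIAL_GAP,
                 attachment_jitter: float = 0.001) -> ShoulderFixture:
    """Build the default synthetic shoulder for one subject.

    Deterministic for fixed arguments; the seed draws ~1 mm Gaussian jitter on
    muscle attachments and ~0.3 mm on ligament attachments (between-subject
    soft-tissue variability).  The humeral head starts internally tangent to
    the glenoid sphere with a clearance of ``initial_gap`` at the deepest
    point of the cavity, centred on the cavity axis.
    """
    spec = spec or AnthropometricSpec()
    tear = tear or TearSpec()
    rng = np.random.default_rng(seed)
    s = spec.body_height / REF_HEIGHT  # length scale
    R_g = spec.glenoid_radius
    R_h = spec.humeral_head_radius
    half = np.deg2rad(spec.glenoid_cap_half_angle)

    # articular geometry: cavity sphere centre sits laterally of the rim plane
    C_g = np.array([0.0, 0.0, R_g * np.cos(half)])
    head_center = C_g - np.array([0.0, 0.0, (R_g - R_h) - initial_gap])
    if initial_gap >= (R_g - R_h) + R_h:  # sanity, never in practice
        raise FixtureValidationError("initial_gap: too large for the articulation")

    glenoid = _spherical_cap(R_g, C_g, 0.0, half, n_rings=16, n_sectors=48)
    labrum_extent = spec.labrum_rim_height / R_g
    labrum = _spherical_cap(R_g, C_g, half, half + labrum_extent, n_rings=6, n_sectors=48)
    head = trimesh.creation.icosphere(subdivisions=4, radius=R_h)
    head.apply_translation(head_center)

    rim_phi = half
    lam = np.linspace(0.0, 2.0 * np.pi, N_CONE_RIM_POINTS, endpoint=False)
    rim_points = C_g + R_g * np.stack(
        [np.sin(rim_phi) * np.cos(lam), np.sin(rim_phi) * np.sin(lam),
         -np.cos(rim_phi) * np.ones_like(lam)], axis=1)

    # glenoid frame from the mesh rim ring (the frame comes out ~identity by
    # construction, but is built from the geometry like any external surface)
    dense_lam = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    dense_rim = C_g + R_g * np.stack(
        [np.sin(rim_phi) * np.cos(dense_lam), np.sin(rim_phi) * np.sin(dense_lam),
         -np.cos(rim_phi) * np.ones_like(dense_lam)], axis=1)
    inferior = C_g + R_g * np.array([0.0, -np.sin(rim_phi), -np.cos(rim_phi)])
    superior = C_g + R_g * np.array([0.0, np.sin(rim_phi), -np.cos(rim_phi)])
    frame = build_glenoid_frame(dense_rim, inferior=inferior, superior=superior)

    # muscles
    mass_scale = spec.body_mass / REF_MASS
    elements: list[MuscleElement] = []
    for name, n_elem, pcsa, oa, ob, ia, ib in _MUSCLE_TABLE:
        oa = np.asarray(oa) * s
        ob = np.asarray(ob) * s
        ia = _resolve_insertion(ia, R_h) * (s if not isinstance(ia, tuple) or ia[0] != "head" else 1.0)
        ib = _resolve_insertion(ib, R_h) * (s if not isinstance(ib, tuple) or ib[0] != "head" else 1.0)
        F0 = SPECIFIC_TENSION * pcsa * mass_scale / n_elem
        fracs = np.linspace(0.0, 1.0, n_elem) if n_elem > 1 else np.array([0.5])
        jit_o = rng.normal(0.0, attachment_jitter, (n_elem, 3))
        jit_i = rng.normal(0.0, attachment_jitter, (n_elem, 3))
        for j, f in enumerate(fracs):
            origin = oa + f * (ob - oa) + jit_o[j]
            insertion = ia + f * (ib - ia) + jit_i[j]
            # keep head-footprint insertions on their attachment sphere
            if np.linalg.norm(insertion) < HEAD_FOOTPRINT_FACTOR * R_h:
                insertion *= HEAD_FOOTPRINT_FACTOR * R_h / np.linalg.norm(insertion)
            elements.append(MuscleElement(
                muscle=name, origin=origin, insertion_local=insertion, F0=F0,
                tear_factor=tear.factors.get(name, 1.0)))

    # ligaments
    lig_jitter = 0.3 * attachment_jitter
    bundles: list[LigamentBundle] = []
    for name, parent, n_spr, k, cal_pose, strain, oa, ob, da, db in _LIGAMENT_TABLE:
        oa = np.asarray(oa) * s
        ob = np.asarray(ob) * s
        da = np.asarray(da, dtype=float)
        db = np.asarray(db, dtype=float)
        fracs = np.linspace(0.0, 1.0, n_spr) if n_spr > 1 else np.array([0.5])
        origins = oa + fracs[:, None] * (ob - oa) + rng.normal(0.0, lig_jitter, (n_spr, 3))
        dirs = da + fracs[:, None] * (db - da)
        dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
        insertions = HEAD_FOOTPRINT_FACTOR * R_h * dirs
        bundles.append(LigamentBundle(
            name=name, parent=parent, origins=origins, insertions_local=insertions,
            stiffness=k, calibration_pose=cal_pose, calibration_strain=strain))

    arm_length = ARM_LENGTH_FRACTION * spec.body_height
    arm_mass = ARM_MASS_FRACTION * spec.body_mass
    arm = ArmSegment(
        mass=arm_mass,
        com_local=np.array([0.0, -ARM_COM_FRACTION * arm_length, 0.0]),
        length=arm_length,
        inertia=np.diag([arm_mass * arm_length**2 / 12.0] * 2 + [1e-4]),
    )

    fixture = ShoulderFixture(
        anthropometrics=spec, tear=tear, seed=seed,
        glenoid_mesh=glenoid, labrum_mesh=labrum, humeral_head_mesh=head,
        glenoid_frame=frame, head_center=head_center, head_radius=R_h,
        initial_gap=initial_gap, muscles=elements, ligaments=bundles,
        arm=arm, cone_rim_points=rim_points)

    assert len(fixture.muscle_names) == 16
    assert fixture.n_muscle_elements == 118
    counts = fixture.ligament_spring_counts
    assert counts == {"superior_gh": 2, "middle_gh": 2, "inferior_gh": 8, "coracohumeral": 5}
    return fixture


def make_motion(peak: float = 30.0, n_cycles: int = 3, frame_rate: float = 5.0,
                cycle_duration: float = 4.0,
                plane_offset: float = SCAPULAR_PLANE_OFFSET_DEG) -> MotionProfile:
    """Smooth repeated 0 -> peak -> 0 elevation cycles in the scapular plane.

    The raised-cosine profile is continuously differentiable across cycle
    boundaries, starts and ends at 0 deg and reaches ``peak`` once per cycle.
    """
    if not (0 < peak <= 180):
        raise ValueError("peak must be in (0, 180] deg")
    if n_cycles < 1 or int(n_cycles) != n_cycles:
        raise ValueError("n_cycles must be a positive integer")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    span = n_cycles * cycle_duration
    n_frames = int(round(span * frame_rate))
    times = np.linspace(0.0, span, n_frames + 1)
    elev = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * (times % cycle_duration) / cycle_duration))
    # guarantee the sampled maxima hit the peak exactly once per cycle
    for c in range(int(n_cycles)):
        tc = (c + 0.5) * cycle_duration
        i = int(np.argmin(np.abs(times - tc)))
        times[i] = tc
        elev[i] = peak
    elev[0] = elev[-1] = 0.0
    frames = tuple((float(t), float(a)) for t, a in zip(times, elev))
    return MotionProfile(frames=frames, n_cycles=int(n_cycles), peak_angle=float(peak),
                         cycle_duration=float(cycle_duration),
                         scapular_plane_offset=float(plane_offset))


def make_loadcases(spec: AnthropometricSpec | None = None) -> list[LoadCase]:
    """The study's handheld-weight battery: 0, 1, 2 and 3 kg."""
    spec = spec or AnthropometricSpec()
    offset = (0.0, -ARM_LENGTH_FRACTION * spec.body_height, 0.0)
    return [LoadCase(handheld_mass=float(m), hand_offset=offset) for m in (0, 1, 2, 3)]


def synth_fluoro_translations(profile: MotionProfile, amplitude: float,
                              noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Fluoroscopy-like measured GH translation series (mm, glenoid frame).

    The noise-free signal tracks elevation: inferior and anterior translation
    proportional to the elevation angle (the pattern seen in healthy
    shoulders), with max |IS| equal to ``amplitude`` and an AP excursion of
    0.8 x amplitude, plus additive Gaussian measurement noise.
    """
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = profile.times
    scale = profile.elevations / profile.peak_angle
    is_mm = -amplitude * scale
    ap_mm = 0.8 * amplitude * scale
    if noise_sd > 0:
        is_mm = is_mm + rng.normal(0.0, noise_sd, len(t))
        ap_mm = ap_mm + rng.normal(0.0, noise_sd, len(t))
    return pd.DataFrame({"time_s": t, "ap_mm": ap_mm, "is_mm": is_mm})


# ---------------------------------------------------------------------------
# model-file export / import
# ---------------------------------------------------------------------------

def export_fixture(fixture: ShoulderFixture, path) -> None:
    """Write meshes (OBJ) and a YAML model file with the documented schema."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, mesh in (("glenoid", fixture.glenoid_mesh), ("labrum", fixture.labrum_mesh),
                       ("humeral_head", fixture.humeral_head_mesh)):
        mesh.export(path / f"{name}.obj")
    model = {
        "anthropometrics": {k: float(getattr(fixture.anthropometrics, k))
                            for k in ("body_height", "body_mass", "humeral_head_radius",
                                      "glenoid_radius", "glenoid_cap_half_angle",
                                      "labrum_rim_height")},
        "tear": fixture.tear.factors,
        "seed": int(fixture.seed),
        "initial_gap": float(fixture.initial_gap),
        "head_center": fixture.head_center.tolist(),
        "head_radius": float(fixture.head_radius),
        "glenoid_frame": fixture.glenoid_frame.to_dict(),
        "cone_rim_points": fixture.cone_rim_points.tolist(),
        "arm": {"mass": float(fixture.arm.mass),
                "com_local": fixture.arm.com_local.tolist(),
                "length": float(fixture.arm.length),
                "inertia": fixture.arm.inertia.tolist()},
        "muscles": [{"muscle": e.muscle, "origin": e.origin.tolist(),
                     "insertion_local": e.insertion_local.tolist(),
                     "F0": float(e.F0),
                     "l_opt": None if e.l_opt is None else float(e.l_opt),
                     "l_half": None if e.l_half is None else float(e.l_half),
                     "tear_factor": float(e.tear_factor)} for e in fixture.muscles],
        "ligaments": [{"name": b.name, "parent": b.parent,
                       "origins": b.origins.tolist(),
                       "insertions_local": b.insertions_local.tolist(),
                       "stiffness": float(b.stiffness),
                       "calibration_pose": list(b.calibration_pose),
                       "calibration_strain": float(b.calibration_strain),
                       "toe_strain": float(b.toe_strain),
                       "slack_lengths": None if b.slack_lengths is None
                       else b.slack_lengths.tolist()} for b in fixture.ligaments],
    }
    with open(path / "model.yaml", "w") as fh:
        yaml.safe_dump(model, fh, sort_keys=False)


def load_fixture(path) -> ShoulderFixture:
    path = Path(path)
    with open(path / "model.yaml") as fh:
        model = yaml.safe_load(fh)
    meshes = {name: trimesh.load(path / f"{name}.obj", process=False)
              for name in ("glenoid", "labrum", "humeral_head")}
    spec = AnthropometricSpec(**model["anthropometrics"])
    tear = TearSpec(**model["tear"])
    muscles = [MuscleElement(muscle=m["muscle"], origin=np.array(m["origin"]),
                             insertion_local=np.array(m["insertion_local"]),
                             F0=m["F0"], l_opt=m["l_opt"], l_half=m.get("l_half"),
                             tear_factor=m["tear_factor"])
               for m in model["muscles"]]
    ligaments = [LigamentBundle(
        name=b["name"], parent=b["parent"], origins=np.array(b["origins"]),
        insertions_local=np.array(b["insertions_local"]), stiffness=b["stiffness"],
        calibration_pose=tuple(b["calibration_pose"]),
        calibration_strain=b["calibration_strain"], toe_strain=b["toe_strain"],
        slack_lengths=None if b["slack_lengths"] is None else np.array(b["slack_lengths"]))
        for b in model["ligaments"]]
    arm = ArmSegment(mass=model["arm"]["mass"], com_local=np.array(model["arm"]["com_local"]),
                     length=model["arm"]["length"], inertia=np.array(model["arm"]["inertia"]))
    return ShoulderFixture(
        anthropometrics=spec, tear=tear, seed=model["seed"],
        glenoid_mesh=meshes["glenoid"], labrum_mesh=meshes["labrum"],
        humeral_head_mesh=meshes["humeral_head"],
        glenoid_frame=Frame.from_dict(model["glenoid_frame"]),
        head_center=np.array(model["head_center"]), head_radius=model["head_radius"],
        initial_gap=model["initial_gap"], muscles=muscles, ligaments=ligaments,
        arm=arm, cone_rim_points=np.array(model["cone_rim_points"]))


def config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
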