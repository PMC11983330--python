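"""Coordinate frames, glenohumeral pose kinematics and path geometry.

The working coordinate system throughout the package is the *glenoid frame*:
``x`` anterior, ``y`` superior, ``z`` lateral (pointing from the glenoid
cavity toward the humerus).  Gravity acts along ``-y``.  Humeral elevation in
the scapular plane is a rotation about the glenoid ``x`` axis through the
nominal humeral-head centre; the three unconstrained translational degrees of
freedom of the joint are expressed as a vector ``u`` (AP, IS, lateral) in the
glenoid frame.

Muscle and ligament paths run from a scapula-fixed origin to a humerus-fixed
insertion and may wrap around the humeral head, modelled as a single spherical
obstacle.  The shortest wrapped path (tangent - great-circle arc - tangent) has
a closed form which is evaluated here, vectorised over many paths at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ORTHO_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised for collinear rim points, endpoints inside the wrap sphere, etc."""


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal coordinate frame.

    ``axes`` rows are the x (anterior+), y (superior+) and z (lateral+,
    glenoid -> humerus) unit vectors expressed in the parent frame.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame axes must be right-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "axes": self.axes.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Frame":
        return cls(np.asarray(d["origin"]), np.asarray(d["axes"]))


@dataclass
class Pose:
    """Primary (angles, deg) plus secondary (translation u, m) GH kinematics."""

    elevation_deg: float = 0.0
    plane_offset_deg: float = 0.0
    axial_deg: float = 0.0
    u: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float).reshape(3)
        if not np.all(np.isfinite([self.elevation_deg, self.plane_offset_deg, self.axial_deg])):
            raise ValueError("pose angles must be finite")
        if np.linalg.norm(self.u) > 0.010 + 1e-12:
            raise ValueError("translation magnitude exceeds the 10 mm search bound")


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-15:
        raise DegenerateGeometryError("cannot normalise a zero vector")
    return v / n


def rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis``."""
    a = _normalize(np.asarray(axis, dtype=float))
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


def build_glenoid_frame(
    rim_points: np.ndarray,
    inferior: np.ndarray | None = None,
    superior: np.ndarray | None = None,
    outward_hint: np.ndarray = (0.0, 0.0, 1.0),
) -> Frame:
    """Construct the glenoid frame from rim points and two landmarks.

    Origin at the rim centroid; ``y`` from the inferior toward the superior rim
    landmark (projected into the rim plane); ``z`` along the outward cap normal
    (fit to the rim plane, signed to agree with ``outward_hint``); ``x = y x z``.
    If the landmarks are omitted they default to the extreme rim points along
    the first principal direction of the rim scatter (inferior = the end with
    the smaller coordinate along that direction).
    """
    pts = np.asarray(rim_points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 rim points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # plane fit: smallest singular vector is the normal
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1e-30):
        raise DegenerateGeometryError("rim points are collinear")
    normal = vt[2]
    hint = np.asarray(outward_hint, dtype=float)
    if normal @ hint < 0:
        normal = -normal
    if inferior is None or superior is None:
        t = centered @ vt[0]
        inferior = pts[int(np.argmin(t))]
        superior = pts[int(np.argmax(t))]
    y = np.asarray(superior, float) - np.asarray(inferior, float)
    y = y - (y @ normal) * normal
    y = _normalize(y)
    x = np.cross(y, normal)
    return Frame(origin=centroid, axes=np.vstack([x, y, normal]))


@dataclass(frozen=True)
class RigidTransform:
    """Rotation ``R`` about a centre ``c`` composed with translation ``u``.

    Maps humerus-local coordinates (relative to the nominal head centre) into
    the glenoid frame: ``p_world = c + u + R @ p_local``.
    """

    R: np.ndarray
    center: np.ndarray
    u: np.ndarray

    def apply_local(self, p_local: np.ndarray) -> np.ndarray:
        p = np.asarray(p_local, dtype=float)
        return self.center + self.u + p @ self.R.T

    def apply_world(self, p_world: np.ndarray) -> np.ndarray:
        """Transform points given in the glenoid frame at the neutral pose."""
        p = np.asarray(p_world, dtype=float)
        return self.center + self.u + (p - self.center) @ self.R.T

    @property
    def head_center(self) -> np.ndarray:
        return self.center + self.u


# humeral long axis in humerus-local coordinates (arm hangs along -y at neutral)
_LONG_AXIS = np.array([0.0, -1.0, 0.0])
# elevation rotates the arm laterally upward in the scapular (y-z) plane
_ELEVATION_AXIS = np.array([1.0, 0.0, 0.0])


def pose_transform(pose: Pose, head_center_neutral: np.ndarray) -> RigidTransform:
    """Rigid transform of the humerus for a given pose.

    Elevation is a rotation about the glenoid-frame x axis through the nominal
    head centre (ball rotation: the centre itself only moves by ``u``);
    ``plane_offset`` tilts the elevation plane about y; ``axial`` rotates about
    the humeral long axis (positive = external rotation of a right humerus).
    """
    th = np.deg2rad(pose.elevation_deg)
    po = np.deg2rad(pose.plane_offset_deg)
    ax = np.deg2rad(pose.axial_deg)
    R_plane = rotation_about([0.0, 1.0, 0.0], po)
    R_elev = rotation_about(R_plane @ _ELEVATION_AXIS, -th)
    R_prim = R_elev @ R_plane
    R_axial = rotation_about(R_prim @ _LONG_AXIS, ax)
    return RigidTransform(R=R_axial @ R_prim, center=np.asarray(head_center_neutral, float), u=pose.u)


def pose_at(profile, t: float, u: np.ndarray, head_center_neutral: np.ndarray,
            plane_offset_deg: float = 0.0, axial_deg: float = 0.0) -> RigidTransform:
    """Humerus transform at time ``t`` of a motion profile with translation ``u``."""
    t0, t1 = profile.frames[0][0], profile.frames[-1][0]
    if not (t0 - 1e-9 <= t <= t1 + 1e-9):
        raise ValueError(f"t={t} outside the profile span [{t0}, {t1}]")
    pose = Pose(elevation_deg=profile.elevation_at(t), plane_offset_deg=plane_offset_deg,
                axial_deg=axial_deg, u=np.asarray(u, float))
    return pose_transform(pose, head_center_neutral)


# ---------------------------------------------------------------------------
# spherical obstacle wrapping
# ---------------------------------------------------------------------------

def wrap_lengths(
    origins: np.ndarray,
    insertions: np.ndarray,
    center: np.ndarray,
    radius: float,
    return_dirs: bool = False,
):
    """Shortest-path lengths around a spherical obstacle, vectorised.

    For each (origin, insertion) pair: the Euclidean distance if the straight
    segment clears the sphere, otherwise the tangent - great-circle-arc -
    tangent length in the plane through both endpoints and the centre.

    With ``return_dirs`` also returns the unit *net pull direction on the
    humerus*: the string's resultant on the body carrying the sphere and the
    insertion is the tension along the departing segment toward the origin
    (from the scapula-side tangent point, or straight from the insertion when
    unwrapped).
    """
    O = np.atleast_2d(np.asarray(origins, dtype=float))
    I = np.atleast_2d(np.asarray(insertions, dtype=float))
    C = np.asarray(center, dtype=float).reshape(3)
    a = O - C
    b = I - C
    da = np.linalg.norm(a, axis=1)
    db = np.linalg.norm(b, axis=1)
    if np.any(da <= radius) or np.any(db <= radius):
        bad = int(np.argmax((da <= radius) | (db <= radius)))
        raise DegenerateGeometryError(
            f"path endpoint {bad} lies inside the wrapping sphere "
            f"(distances {da[bad]:.4g}/{db[bad]:.4g} vs radius {radius:.4g})"
        )
    chord = I - O
    Lc = np.linalg.norm(chord, axis=1)
    Lc_safe = np.where(Lc < 1e-15, 1.0, Lc)
    # closest approach of the segment to the centre
    s = np.clip(np.einsum("ij,ij->i", C - O, chord) / Lc_safe**2, 0.0, 1.0)
    closest = O + s[:, None] * chord
    dmin = np.linalg.norm(closest - C, axis=1)

    cosg = np.clip(np.einsum("ij,ij->i", a, b) / (da * db), -1.0, 1.0)
    gamma = np.arccos(cosg)
    alpha_a = np.arccos(np.clip(radius / da, -1.0, 1.0))
    alpha_b = np.arccos(np.clip(radius / db, -1.0, 1.0))
    arc = gamma - alpha_a - alpha_b
    wraps = (dmin < radius) & (arc > 0.0)

    tA = np.sqrt(np.maximum(da**2 - radius**2, 0.0))
    tB = np.sqrt(np.maximum(db**2 - radius**2, 0.0))
    lengths = np.where(wraps, tA + tB + radius * np.maximum(arc, 0.0), Lc)

    if not return_dirs:
        return lengths, wraps

    # direction of net pull on the humerus: toward the origin from the first
    # path vertex on the scapula side (tangent point T_A when wrapped)
    dirs = np.empty_like(O)
    straight = ~wraps
    dirs[straight] = (O[straight] - I[straight]) / Lc_safe[straight, None]
    if np.any(wraps):
        aw = a[wraps]
        bw = b[wraps]
        daw = da[wraps][:, None]
        e1 = aw / daw
        b_perp = bw - np.einsum("ij,ij->i", bw, e1)[:, None] * e1
        e2 = b_perp / np.linalg.norm(b_perp, axis=1)[:, None]
        ang = alpha_a[wraps][:, None]
        TA = C + radius * (np.cos(ang) * e1 + np.sin(ang) * e2)
        d = O[wraps] - TA
        dirs[wraps] = d / np.linalg.norm(d, axis=1)[:, None]
    return lengths, wraps, dirs


def path_length_with_sphere_wrap(origin, insertion, sphere_center, sphere_radius):
    """Single-path wrapped length plus the path polyline (m).

    Returns ``(length, polyline)`` where the polyline is the origin, the two
    tangent points with intermediate arc samples when the path wraps, and the
    insertion.
    """
    O = np.asarray(origin, dtype=float).reshape(3)
    I = np.asarray(insertion, dtype=float).reshape(3)
    C = np.asarray(sphere_center, dtype=float).reshape(3)
    r = float(sphere_radius)
    lengths, wraps = wrap_lengths(O[None], I[None], C, r)
    if not wraps[0]:
        return float(lengths[0]), np.vstack([O, I])
    a, b = O - C, I - C
    da, db = np.linalg.norm(a), np.linalg.norm(b)
    e1 = a / da
    b_perp = b - (b @ e1) * e1
    e2 = b_perp / np.linalg.norm(b_perp)
    gamma = np.arccos(np.clip((a @ b) / (da * db), -1, 1))
    phi_a = np.arccos(r / da)
    phi_b = gamma - np.arccos(r / db)
    phis = np.linspace(phi_a, phi_b, 17)
    arc_pts = C + r * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
    return float(lengths[0]), np.vstack([O, arc_pts, I])


def rotated_about(points: np.ndarray, axis: np.ndarray, angle_rad: float,
                  center: np.ndarray) -> np.ndarray:
    """Rotate points about an axis through ``center`` (used for tendon-excursion
    moment arms and the ROM sweep)."""
    R = rotation_about(axis, angle_rad)
    p = np.asarray(points, dtype=float)
    c = np.asarray(center, dtype=float)
    return c + (p - c) @ R.T
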