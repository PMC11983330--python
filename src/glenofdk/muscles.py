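"""Hill-type muscle elements: instantaneous strength, tears, operating range.

Each anatomical muscle is discretised into several elements (line actuators)
to spread its line of action across the attachment footprint.  The
instantaneous strength of an element is

    S = tear_factor * F0 * f_l(l~) * f_v(v~)

with ``F0`` the nominal (PCSA-derived) strength, ``f_l`` the active
force-length curve evaluated at the normalised path length ``l~ = l/l_opt``
and ``f_v`` the force-velocity curve.  The simulated task is quasi-static, so
``v~ = 0`` and ``f_v = 1`` throughout the trials; the curve is kept for
completeness.

Rotator-cuff tears scale strength per muscle: 1 (intact), 0.5 (partial-
thickness tear), 0 (full-thickness tear, the muscle is inactivated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .geometry import Pose, pose_transform, wrap_lengths

log = logging.getLogger(__name__)

ROTATOR_CUFF = ("supraspinatus", "infraspinatus", "subscapularis", "teres_minor")

FL_LOWER, FL_UPPER = 0.5, 1.5  # support of the active force-length curve
FV_MAX = 1.4  # eccentric plateau of the force-velocity curve


#: half-width of the normalised operating range: the ROM excursion maps to
#: l~ in [1 - OPERATING_HALF_SPAN, 1 + OPERATING_HALF_SPAN]
OPERATING_HALF_SPAN = 0.4


@dataclass
class MuscleElement:
    muscle: str
    origin: np.ndarray  # scapula/thorax-fixed, glenoid frame
    insertion_local: np.ndarray  # humerus-fixed, relative to head centre
    F0: float  # nominal strength, N
    l_opt: float | None = None  # optimal (reference) path length, m
    l_half: float | None = None  # half-excursion over the ROM sweep, m
    tear_factor: float = 1.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.insertion_local = np.asarray(self.insertion_local, dtype=float).reshape(3)
        if self.F0 <= 0:
            raise ValueError(f"{self.muscle}: F0 must be > 0")
        if self.tear_factor not in (0.0, 0.5, 1.0):
            raise ValueError(f"{self.muscle}: tear factor must be 0, 0.5 or 1")


def force_length(l_norm):
    """Active force-length curve: quadratic bump on [0.5, 1.5], peak 1 at l~=1."""
    l = np.asarray(l_norm, dtype=float)
    return np.maximum(0.0, 1.0 - ((l - 1.0) / (FL_UPPER - 1.0)) ** 2)


def force_velocity(v_norm):
    """Clipped Hill curve; ``v~`` positive = shortening, in l_opt/s.

    f_v(0) = 1; concentric branch is the Hill hyperbola, eccentric branch
    rises to the 1.4 plateau.
    """
    v = np.asarray(v_norm, dtype=float)
    conc = np.maximum(0.0, (1.0 - v) / (1.0 + 4.0 * v))
    ecc = np.minimum(FV_MAX, 1.0 - 1.5 * v)
    return np.where(v >= 0.0, conc, ecc)


def strength_at(element: MuscleElement, l_norm: float, v_norm: float = 0.0) -> float:
    """Instantaneous strength (N) of a calibrated element."""
    if element.l_opt is None:
        raise RuntimeError(f"{element.muscle}: element not calibrated (no l_opt)")
    return float(element.tear_factor * element.F0
                 * force_length(l_norm) * force_velocity(v_norm))


def apply_tear(fixture, tear) -> "ShoulderFixture":  # noqa: F821
    """Return a fixture whose named muscles carry the tear strength factors."""
    present = {e.muscle for e in fixture.muscles}
    factors = tear.factors
    unknown = set(factors) - present
    if unknown:
        raise ValueError(f"tear names unknown muscles: {sorted(unknown)}")
    new = [replace(e, tear_factor=factors.get(e.muscle, 1.0)) for e in fixture.muscles]
    return fixture.with_muscles(new, tear=tear)


# range-of-motion sweep used for the operating-range calibration (deg)
ROM_ELEVATION = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)
ROM_PLANE = (-30.0, 0.0, 30.0, 60.0, 90.0)   # elevation-plane offsets toward flexion
ROM_AXIAL = (-70.0, -30.0, 10.0, 50.0, 90.0)  # internal (-) to external (+) rotation


def normalized_length(lengths, l_opt, l_half):
    """Normalised fibre length of the span-calibrated operating range.

    The ROM excursion [l_opt - l_half, l_opt + l_half] maps affinely onto
    l~ in [0.6, 1.4], symmetric about 1 (the excursion midpoint is the
    optimal length); a zero-excursion element sits at l~ = 1 everywhere.
    """
    L = np.asarray(lengths, dtype=float)
    half = np.asarray(l_half, dtype=float)
    safe = np.where(half < 1e-12, 1.0, half)
    out = 1.0 + OPERATING_HALF_SPAN * (L - np.asarray(l_opt, dtype=float)) / safe
    return np.where(half < 1e-12, 1.0, out)


def calibrate_muscle_operating_range(fixture) -> "ShoulderFixture":  # noqa: F821
    """Calibrate each element's operating range from its path-length excursion
    over the full shoulder range of motion.

    The sampled range covers 0-180 deg elevation across elevation planes from
    extension to flexion and -70 to +90 deg axial rotation.  ``l_opt`` is the
    excursion midpoint (mapped to l~ = 1) and the excursion spans [0.6, 1.4]
    of normalised length, inside the force-length support everywhere.
    Elements with zero excursion keep their current length as ``l_opt`` and
    operate at l~ = 1 (with a warning).
    """
    origins = np.array([e.origin for e in fixture.muscles])
    ins_local = np.array([e.insertion_local for e in fixture.muscles])
    lmin = np.full(len(origins), np.inf)
    lmax = np.full(len(origins), -np.inf)
    for elev in ROM_ELEVATION:
        for plane in ROM_PLANE:
            for axial in ROM_AXIAL:
                T = pose_transform(
                    Pose(elevation_deg=elev, plane_offset_deg=plane, axial_deg=axial),
                    fixture.head_center)
                L, _ = wrap_lengths(origins, T.apply_local(ins_local),
                                    T.head_center, fixture.head_radius)
                lmin = np.minimum(lmin, L)
                lmax = np.maximum(lmax, L)
    l_opt = 0.5 * (lmin + lmax)
    l_half = 0.5 * (lmax - lmin)
    flat = l_half < 1e-12
    if np.any(flat):
        log.warning("%d muscle elements have zero excursion over the ROM", int(flat.sum()))
    new = [replace(e, l_opt=float(l_opt[i]), l_half=float(l_half[i]))
           for i, e in enumerate(fixture.muscles)]
    return fixture.with_muscles(new)
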