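"""Tension-only glenohumeral and coracohumeral ligament bundles.

Each bundle is a set of discrete spring elements from a scapula-fixed origin
to a humerus-fixed insertion, routed around the spherical humeral head.  The
constitutive law is the classic slack / quadratic-toe / linear form: with
engineering strain ``e = (L - L0)/L0`` and toe extent ``e_t``,

    T(e) = 0                      e <= 0
         = k e^2 / (2 e_t)        0 < e <= e_t
         = k (e - e_t/2)          e > e_t

which is C1 at the toe/linear junction.  ``k`` is the bundle elastic
stiffness in newtons per unit strain, split equally across the bundle's
springs so the bundle-level stiffness equals the published value.

Slack lengths are not material constants; they are calibrated per subject by
placing the humerus in a reference pose with a known strain and setting
``L0 = L_pose / (1 + e_ref)`` for every spring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import wrap_lengths

DEFAULT_TOE_STRAIN = 0.03


class UncalibratedLigamentError(RuntimeError):
    pass


@dataclass
class LigamentBundle:
    """Discretised ligament (or one portion of the inferior GH ligament)."""

    name: str
    parent: str  # anatomical ligament this belongs to (inferior GH has 3 portions)
    origins: np.ndarray  # (n, 3) scapula-fixed, glenoid frame
    insertions_local: np.ndarray  # (n, 3) humerus-fixed, relative to head centre
    stiffness: float  # N per unit strain, whole bundle
    calibration_pose: tuple[float, float]  # (abduction deg, axial rotation deg)
    calibration_strain: float
    toe_strain: float = DEFAULT_TOE_STRAIN
    slack_lengths: np.ndarray | None = None

    def __post_init__(self):
        self.origins = np.atleast_2d(np.asarray(self.origins, dtype=float))
        self.insertions_local = np.atleast_2d(np.asarray(self.insertions_local, dtype=float))
        if self.stiffness <= 0:
            raise ValueError(f"{self.name}: stiffness must be > 0")
        if self.toe_strain < 0:
            raise ValueError(f"{self.name}: toe_strain must be >= 0")
        if self.slack_lengths is not None:
            self.slack_lengths = np.asarray(self.slack_lengths, dtype=float)
            if np.any(self.slack_lengths <= 0):
                raise ValueError(f"{self.name}: slack lengths must be > 0")

    @property
    def n_springs(self) -> int:
        return len(self.origins)

    @property
    def calibrated(self) -> bool:
        return self.slack_lengths is not None


def spring_tension(k_spring: float, length, slack_length, toe_strain: float = DEFAULT_TOE_STRAIN):
    """Tension (N) of one spring; vectorised over lengths/slack lengths."""
    L = np.asarray(length, dtype=float)
    L0 = np.asarray(slack_length, dtype=float)
    if np.any(L0 <= 0):
        raise ValueError("slack length must be > 0")
    eps = (L - L0) / L0
    if toe_strain > 0:
        toe = k_spring * eps**2 / (2.0 * toe_strain)
        lin = k_spring * (eps - toe_strain / 2.0)
        T = np.where(eps <= toe_strain, toe, lin)
    else:
        T = k_spring * eps
    return np.where(eps <= 0.0, 0.0, T)


def ligament_tension(bundle: LigamentBundle, lengths) -> np.ndarray:
    """Per-spring tensions of a calibrated bundle at the given lengths."""
    if not bundle.calibrated:
        raise UncalibratedLigamentError(f"bundle {bundle.name} has no slack lengths yet")
    k_spring = bundle.stiffness / bundle.n_springs
    return spring_tension(k_spring, lengths, bundle.slack_lengths, bundle.toe_strain)


def bundle_lengths(bundle: LigamentBundle, transform, wrap_radius: float):
    """Wrapped spring lengths and pull directions on the humerus at a pose."""
    ins_world = transform.apply_local(bundle.insertions_local)
    return wrap_lengths(bundle.origins, ins_world, transform.head_center,
                        wrap_radius, return_dirs=True)


def calibrate_slack_lengths(fixture) -> "ShoulderFixture":  # noqa: F821
    """Set every spring's slack length from its bundle's calibration pose.

    The humerus is placed at the bundle's (abduction, axial rotation) with zero
    translation, the wrapped spring lengths are evaluated, and
    ``L0 = L / (1 + calibration_strain)``, so re-evaluating the strain at that
    pose returns the prescribed value exactly.
    """
    from .geometry import Pose, pose_transform

    new_bundles = []
    for bundle in fixture.ligaments:
        abd, axial = bundle.calibration_pose
        T = pose_transform(Pose(elevation_deg=abd, axial_deg=axial), fixture.head_center)
        lengths, _, _ = bundle_lengths(bundle, T, fixture.head_radius)
        L0 = lengths / (1.0 + bundle.calibration_strain)
        new_bundles.append(replace(bundle, slack_lengths=L0))
    return fixture.with_ligaments(new_bundles)


def bundle_strains(bundle: LigamentBundle, lengths) -> np.ndarray:
    if not bundle.calibrated:
        raise UncalibratedLigamentError(f"bundle {bundle.name} has no slack lengths yet")
    return (np.asarray(lengths) - bundle.slack_lengths) / bundle.slack_lengths
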