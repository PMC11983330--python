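"""Elastic-foundation contact between the humeral head and glenoid/labrum.

The contact law treats the master surface (glenoid bone or labrum rim, fixed
in the glenoid frame) as a bed of independent compliant columns: each slave
facet (humeral head) that penetrates the master contributes its penetration
depth times its area projected onto the master normal.  The total force
magnitude is ``pressure_module x penetration_volume``; its direction is the
depth-weighted average of the master facet normals at the contact points, so a
conforming patch pushes the slave out of the master along the distributed
normal field rather than a single contact normal.

Penetration depth is measured by projecting slave facet centroids onto the
master with a nearest-point query and signing the offset by the master
outward normal (the side facing the joint space).  This is robust for the
near-congruent spherical caps of the glenohumeral joint, where ray casting
grazes badly.  Facets whose outward normal does not oppose the master normal
(the far side of the head) are excluded, as is any depth beyond
``max_depth`` which can only arise from a non-physical transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nearest import MeshNearest

log = logging.getLogger(__name__)

#: bone-on-bone pressure module, N/m^3
BONE_PRESSURE_MODULE = 9.3e9
#: humeral head on labrum pressure module, N/m^3
LABRUM_PRESSURE_MODULE = 0.11e9


@dataclass
class ContactModel:
    """One master/slave surface pair with an elastic-foundation pressure module."""

    pressure_module: float
    master: "trimesh.Trimesh"  # noqa: F821 - typing only
    slave: "trimesh.Trimesh"  # noqa: F821
    max_depth: float = 0.005
    _query: MeshNearest = field(init=False, repr=False)
    _slave_centroids: np.ndarray = field(init=False, repr=False)
    _slave_normals: np.ndarray = field(init=False, repr=False)
    _slave_areas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.pressure_module <= 0:
            raise ValueError("pressure_module must be > 0")
        self._query = MeshNearest(self.master)
        areas = np.asarray(self.slave.area_faces, dtype=float)
        good = areas > 1e-16
        n_bad = int((~good).sum())
        if n_bad:
            log.warning("ignoring %d degenerate slave facets", n_bad)
        self._slave_vertices = np.asarray(self.slave.vertices, dtype=float)
        self._slave_faces = np.asarray(self.slave.faces)[good]
        self._slave_normals = np.asarray(self.slave.face_normals, dtype=float)[good]
        self._slave_areas = areas[good]
        # pre-cull region: slave geometry beyond this sphere can never reach
        # the master within the translation search bound
        mc = np.asarray(self.master.vertices).mean(axis=0)
        mr = np.linalg.norm(np.asarray(self.master.vertices) - mc, axis=1).max()
        self._cull_center = mc
        self._cull_radius = mr + 0.012


@dataclass
class ContactPatch:
    """Resultant of one elastic-foundation evaluation."""

    penetration_volume: float
    force: np.ndarray
    moment: np.ndarray  # about the glenoid origin
    center_of_pressure: np.ndarray | None
    facet_depths: np.ndarray


def penetration_volume(model: ContactModel, transform) -> tuple[float, dict]:
    """Penetration volume (m^3) of the transformed slave into the master.

    ``transform`` maps neutral-pose glenoid-frame points of the slave to their
    current position (a :class:`~glenofdk.geometry.RigidTransform` or a
    callable on (n,3) arrays).  Also returns the per-facet foundation data
    used by :func:`contact_wrench`.
    """
    apply = transform.apply_world if hasattr(transform, "apply_world") else transform
    verts = apply(model._slave_vertices)
    n_faces = len(model._slave_faces)
    data = {"depths": np.zeros(n_faces), "points": None, "normals": None,
            "areas": None, "proj": None}
    # cull vertices that cannot reach the master
    near_v = np.linalg.norm(verts - model._cull_center, axis=1) <= model._cull_radius
    if not np.any(near_v):
        return 0.0, data
    idx = np.flatnonzero(near_v)
    nearest, faces = model._query.query(verts[idx])
    mn_v = model._query.face_normals[faces]
    d = np.einsum("ij,ij->i", nearest - verts[idx], mn_v)
    vertex_depth = np.zeros(len(verts))
    vertex_depth[idx] = np.clip(d, 0.0, model.max_depth)
    vertex_point = np.zeros_like(verts)
    vertex_point[idx] = nearest
    vertex_mn = np.zeros_like(verts)
    vertex_mn[idx] = mn_v

    # facet depth = mean of its vertex depths (vertices sample the true
    # surface; straddling facets get graded partial volume)
    fd = vertex_depth[model._slave_faces]
    touched = fd.max(axis=1) > 0.0
    if not np.any(touched):
        return 0.0, data
    fidx = np.flatnonzero(touched)
    tri = model._slave_faces[fidx]
    depth = fd[fidx].mean(axis=1)
    mn = vertex_mn[tri].sum(axis=1)
    nrm = np.linalg.norm(mn, axis=1)
    mn = mn / np.where(nrm < 1e-30, 1.0, nrm)[:, None]
    # rotate slave facet normals (rigid: translation leaves them unchanged)
    if hasattr(transform, "R"):
        sn = model._slave_normals[fidx] @ transform.R.T
    else:
        sn = model._slave_normals[fidx]
    opposing = np.einsum("ij,ij->i", sn, mn)  # ~ -1 for facing surfaces
    facing = opposing < 0.0
    depth = np.where(facing, depth, 0.0)
    proj_area = model._slave_areas[fidx] * np.abs(np.clip(opposing, -1.0, 0.0))
    vol = float(np.sum(depth * proj_area))
    full_depth = np.zeros(n_faces)
    full_depth[fidx] = depth
    points = vertex_point[tri].mean(axis=1)
    data.update(depths=full_depth, points=points, normals=mn,
                areas=proj_area, proj=depth)
    return vol, data


def contact_wrench(model: ContactModel, transform, origin=np.zeros(3)) -> ContactPatch:
    """Elastic-foundation resultant: force, moment about ``origin``, volume.

    Force magnitude is exactly ``pressure_module x penetration_volume``; the
    direction is the depth-weighted average of master facet normals at the
    contact points (pushing the slave out of the master).
    """
    vol, data = penetration_volume(model, transform)
    if vol <= 0.0:
        return ContactPatch(0.0, np.zeros(3), np.zeros(3), None, data["depths"])
    w = data["proj"] * data["areas"]  # per-facet penetration volumes
    direction = (w[:, None] * data["normals"]).sum(axis=0)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-30:
        return ContactPatch(vol, np.zeros(3), np.zeros(3), None, data["depths"])
    direction /= nrm
    force = model.pressure_module * vol * direction
    cop = (w[:, None] * data["points"]).sum(axis=0) / w.sum()
    moment = np.cross(cop - np.asarray(origin, float), force)
    return ContactPatch(vol, force, moment, cop, data["depths"])
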