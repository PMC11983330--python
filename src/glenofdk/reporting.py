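"""Outcome measures: translations, forces, FDK-vs-default comparison, export.

Conventions: joint reactions are reported on the scapula (glenoid side) and
decomposed in the glenoid frame as compressive (positive pressing the humerus
into the glenoid, i.e. along -z), anterior-posterior shear (anterior +x
positive) and inferior-superior shear (superior +y positive).  Translations
are the AP/IS components of u in millimetres.  Only converged frames enter
summary statistics; unconverged frames are counted and reported separately.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fixtures import config_hash
from .geometry import Frame
from .solver import TrialResult


class EmptySummaryError(RuntimeError):
    """No converged frames to summarise."""


def tear_group_label(tear) -> str:
    """healthy / partial / full taxonomy from the tear strength factors."""
    return tear.group


def decompose_joint_reaction(reaction: np.ndarray, frame: Frame) -> tuple[float, float, float]:
    """(compressive, AP shear, IS shear) of a joint reaction vector.

    ``reaction`` is the force on the scapula in the parent frame; compressive
    is positive when it presses the humerus into the glenoid (against the
    lateral-outward z axis of ``frame``).
    """
    r = np.asarray(reaction, dtype=float).reshape(3)
    comp = -float(r @ frame.z)
    ap = float(r @ frame.x)
    is_ = float(r @ frame.y)
    return comp, ap, is_


def scapula_reaction(frame_result) -> np.ndarray:
    """Joint reaction on the scapula = minus the reaction on the humerus."""
    return -np.asarray(frame_result.joint_reaction, dtype=float)


@dataclass
class TranslationSummary:
    max_abs_is_mm: float  # mean over cycles of the per-cycle max |IS|
    max_abs_ap_mm: float
    per_cycle_is_mm: list
    per_cycle_ap_mm: list
    path_ap_mm: np.ndarray  # per converged frame, for translation-path plots
    path_is_mm: np.ndarray
    n_converged: int
    n_frames: int


def summarize_translations(trial: TrialResult) -> TranslationSummary:
    """Per-cycle maxima of |IS| and |AP| translation, averaged over cycles."""
    frames = trial.converged_frames
    if not frames:
        raise EmptySummaryError("trial has no converged frames")
    Tc = trial.profile.cycle_duration
    per_cycle_is, per_cycle_ap = [], []
    for c in range(trial.profile.n_cycles):
        cyc = [f for f in frames if c * Tc - 1e-9 <= f.time <= (c + 1) * Tc + 1e-9]
        if not cyc:
            continue
        per_cycle_ap.append(max(abs(f.u[0]) for f in cyc) * 1e3)
        per_cycle_is.append(max(abs(f.u[1]) for f in cyc) * 1e3)
    return TranslationSummary(
        max_abs_is_mm=float(np.mean(per_cycle_is)),
        max_abs_ap_mm=float(np.mean(per_cycle_ap)),
        per_cycle_is_mm=per_cycle_is, per_cycle_ap_mm=per_cycle_ap,
        path_ap_mm=np.array([f.u[0] * 1e3 for f in frames]),
        path_is_mm=np.array([f.u[1] * 1e3 for f in frames]),
        n_converged=len(frames), n_frames=len(trial.frames))


def max_abs_is(series: pd.DataFrame) -> float:
    """Max |IS| (mm) of a measured-translation series (columns time_s, ap_mm, is_mm)."""
    return float(series["is_mm"].abs().max())


def muscle_force_table(trial: TrialResult, fixture) -> pd.Series:
    """Per-muscle maximum total force (N) over converged frames."""
    frames = trial.converged_frames
    if not frames:
        raise EmptySummaryError("trial has no converged frames")
    names = [e.muscle for e in fixture.muscles]
    df = pd.DataFrame([f.muscle_forces for f in frames], columns=names)
    return df.T.groupby(level=0).sum().max(axis=1).reindex(fixture.muscle_names)


def ligament_table(trial: TrialResult, fixture) -> pd.DataFrame:
    """Per-bundle maximum tension (N) and strain (%) over converged frames."""
    frames = trial.converged_frames
    if not frames:
        raise EmptySummaryError("trial has no converged frames")
    rows = []
    k = 0
    for b in fixture.ligaments:
        sl = slice(k, k + b.n_springs)
        k += b.n_springs
        tension = max(float(f.ligament_tensions[sl].sum()) for f in frames)
        strain = max(float(f.ligament_strains[sl].max()) for f in frames)
        rows.append({"bundle": b.name, "max_tension_n": tension,
                     "max_strain_pct": strain * 100.0})
    return pd.DataFrame(rows).set_index("bundle")


def reaction_at_max_elevation(trial: TrialResult, frame: Frame) -> dict:
    """Joint-reaction triple (on the scapula) at the converged frame of
    highest elevation, plus its magnitude."""
    frames = trial.converged_frames
    if not frames:
        raise EmptySummaryError("trial has no converged frames")
    top = max(frames, key=lambda f: f.elevation_deg)
    r = scapula_reaction(top)
    comp, ap, is_ = decompose_joint_reaction(r, frame)
    return {"elevation_deg": top.elevation_deg, "compressive_n": comp,
            "ap_shear_n": ap, "is_shear_n": is_,
            "total_n": float(np.linalg.norm(r))}


@dataclass
class SummaryStats:
    max_abs_is_mm: float
    max_abs_ap_mm: float
    muscle_max_n: dict
    ligament_max: dict
    reaction: dict
    n_converged: int
    n_frames: int
    failed: bool


def summarize_trial(trial: TrialResult, fixture) -> SummaryStats:
    tr = summarize_translations(trial)
    lig = ligament_table(trial, fixture)
    return SummaryStats(
        max_abs_is_mm=tr.max_abs_is_mm, max_abs_ap_mm=tr.max_abs_ap_mm,
        muscle_max_n=muscle_force_table(trial, fixture).to_dict(),
        ligament_max=lig.to_dict(orient="index"),
        reaction=reaction_at_max_elevation(trial, fixture.glenoid_frame),
        n_converged=tr.n_converged, n_frames=tr.n_frames, failed=trial.failed)


def compare_models(fdk: TrialResult, default: TrialResult, fixture) -> dict:
    """Paired FDK-vs-default outcome table (differences are FDK - default)."""
    if fdk.mode != "fdk" or default.mode != "default":
        raise ValueError("expected one fdk-mode and one default-mode trial")
    if (fdk.loadcase != default.loadcase) or (fdk.profile != default.profile):
        raise ValueError("trials must share fixture, motion and load case")
    mf = muscle_force_table(fdk, fixture)
    md = muscle_force_table(default, fixture)
    muscles = pd.DataFrame({"fdk_n": mf, "default_n": md, "diff_n": mf - md})
    rf = reaction_at_max_elevation(fdk, fixture.glenoid_frame)
    rd = reaction_at_max_elevation(default, fixture.glenoid_frame)
    tf = summarize_translations(fdk)
    td = summarize_translations(default)
    return {
        "muscles": muscles,
        "reaction_fdk": rf, "reaction_default": rd,
        "reaction_diff": {k: rf[k] - rd[k] for k in ("compressive_n", "ap_shear_n",
                                                     "is_shear_n", "total_n")},
        "translations_fdk_mm": {"is": tf.max_abs_is_mm, "ap": tf.max_abs_ap_mm},
        "translations_default_mm": {"is": td.max_abs_is_mm, "ap": td.max_abs_ap_mm},
    }


def trial_to_frame_table(trial: TrialResult, fixture) -> pd.DataFrame:
    """Per-frame table: kinematics, residuals, per-muscle forces, per-bundle
    tensions/strains and the decomposed joint reaction."""
    names = fixture.muscle_names
    el_names = [e.muscle for e in fixture.muscles]
    rows = []
    for f in trial.frames:
        row = {
            "time_s": f.time, "elevation_deg": f.elevation_deg,
            "u_ap_mm": f.u[0] * 1e3, "u_is_mm": f.u[1] * 1e3, "u_lat_mm": f.u[2] * 1e3,
            "residual_n": f.residual_norm, "converged": f.converged,
            "failure_mode": f.failure_mode,
        }
        per_muscle = pd.Series(f.muscle_forces, index=el_names).groupby(level=0).sum()
        for name in names:
            row[f"force_{name}_n"] = float(per_muscle.get(name, 0.0))
        k = 0
        for b in fixture.ligaments:
            sl = slice(k, k + b.n_springs)
            k += b.n_springs
            row[f"tension_{b.name}_n"] = float(f.ligament_tensions[sl].sum())
            row[f"strain_{b.name}_pct"] = float(f.ligament_strains[sl].max() * 100.0)
        comp, ap, is_ = decompose_joint_reaction(scapula_reaction(f), fixture.glenoid_frame)
        row.update(comp_n=comp, ap_shear_n=ap, is_shear_n=is_)
        rows.append(row)
    return pd.DataFrame(rows)


def export_results(trials: list[tuple[str, TrialResult]], fixture, path,
                   seed: int | None = None) -> dict:
    """Write per-frame CSVs, per-trial summary JSON and a run manifest.

    ``trials`` is a list of (label, TrialResult).  Returns the manifest.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = {
        "fixture": fixture.fingerprint(),
        "trials": [{"label": lbl, "mode": t.mode,
                    "handheld_mass": t.loadcase.handheld_mass,
                    "n_frames": len(t.frames)} for lbl, t in trials],
        "seed": seed,
    }
    manifest = {
        "config_hash": config_hash(cfg),
        "config": cfg,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    for label, trial in trials:
        trial_to_frame_table(trial, fixture).to_csv(path / f"{label}_frames.csv", index=False)
        try:
            stats = summarize_trial(trial, fixture)
            summary = {
                "mode": trial.mode, "tear_group": trial.tear_group,
                "handheld_mass": trial.loadcase.handheld_mass,
                "failed": trial.failed,
                "max_abs_is_mm": stats.max_abs_is_mm,
                "max_abs_ap_mm": stats.max_abs_ap_mm,
                "muscle_max_n": stats.muscle_max_n,
                "ligament_max": stats.ligament_max,
                "reaction": stats.reaction,
                "n_converged": stats.n_converged, "n_frames": stats.n_frames,
            }
        except EmptySummaryError:
            summary = {"mode": trial.mode, "failed": True, "n_converged": 0,
                       "n_frames": len(trial.frames)}
        with open(path / f"{label}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
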