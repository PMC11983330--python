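"""Outcome measures: decomposition, summaries, comparison, export."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from glenofdk.fixtures import LoadCase, TearSpec, make_loadcases, make_motion
from glenofdk.geometry import Frame, rotation_about
from glenofdk.reporting import (
    EmptySummaryError,
    compare_models,
    decompose_joint_reaction,
    export_results,
    max_abs_is,
    scapula_reaction,
    summarize_translations,
    trial_to_frame_table,
)
from glenofdk.solver import EquilibriumResult, TrialResult

IDENTITY = Frame(origin=np.zeros(3), axes=np.eye(3))


def _frame_result(t, elev, u, n_elem=118, n_springs=17, converged=True,
                  reaction=(0, 0, 0)):
    return EquilibriumResult(
        time=t, elevation_deg=elev, u=np.asarray(u, float),
        muscle_forces=np.zeros(n_elem), ligament_tensions=np.zeros(n_springs),
        ligament_strains=np.zeros(n_springs), contact_force=np.zeros(3),
        contact_volume=0.0, joint_reaction=np.asarray(reaction, float),
        residual_norm=0.0, torque_residual=0.0, converged=converged)


def _trial(frames, mode="fdk", mass=0.0, n_cycles=1, cycle=4.0):
    profile = make_motion(peak=30, n_cycles=n_cycles, frame_rate=5.0,
                          cycle_duration=cycle)
    return TrialResult(mode=mode, loadcase=LoadCase(handheld_mass=mass),
                       profile=profile, tear_group="healthy", frames=frames)


class TestDecomposition:
    def test_pure_compression(self):
        comp, ap, is_ = decompose_joint_reaction([0, 0, -100.0], IDENTITY)
        assert (comp, ap, is_) == (100.0, 0.0, 0.0)

    def test_superior_shear(self):
        comp, ap, is_ = decompose_joint_reaction([0, 50.0, 0], IDENTITY)
        assert is_ == 50.0 and comp == 0.0 and ap == 0.0

    def test_covariant_under_joint_rotation(self):
        R = rotation_about([0.3, 1.0, -0.2], 0.8)
        reaction = np.array([12.0, -34.0, 56.0])
        frame = Frame(origin=np.zeros(3), axes=np.eye(3) @ R.T)
        assert np.allclose(decompose_joint_reaction(R @ reaction, frame),
                           decompose_joint_reaction(reaction, IDENTITY))

    def test_scapula_reaction_is_newtons_third_law(self):
        f = _frame_result(0, 0, [0, 0, 0], reaction=(1.0, -2.0, 3.0))
        assert np.allclose(scapula_reaction(f), [-1.0, 2.0, -3.0])


class TestGroupLabels:
    @pytest.mark.parametrize("s,i,b", list(itertools.product([0.0, 0.5, 1.0], repeat=3)))
    def test_taxonomy_total_on_rc_combinations(self, s, i, b):
        tear = TearSpec(supraspinatus=s, infraspinatus=i, subscapularis=b)
        vals = (s, i, b)
        if 0.0 in vals:
            assert tear.group == "full"
        elif 0.5 in vals:
            assert tear.group == "partial"
        else:
            assert tear.group == "healthy"

    def test_teres_minor_counts_too(self):
        assert TearSpec(teres_minor=0.5).group == "partial"
        assert TearSpec(teres_minor=0.0).group == "full"


class TestTranslationSummaries:
    def test_constant_offset(self):
        frames = [_frame_result(t, 0.0, [0.0, 1.2e-3, 0.0]) for t in (0, 1, 2, 3)]
        s = summarize_translations(_trial(frames))
        assert s.max_abs_is_mm == pytest.approx(1.2)
        assert s.max_abs_ap_mm == pytest.approx(0.0)

    def test_reorder_within_cycle_invariant(self):
        us = [[0.3e-3, -0.9e-3, 0], [-0.2e-3, 1.4e-3, 0], [0.5e-3, 0.1e-3, 0]]
        frames = [_frame_result(t, 0.0, u) for t, u in zip((0, 1, 2), us)]
        shuffled = [frames[2], frames[0], frames[1]]
        a = summarize_translations(_trial(frames))
        b = summarize_translations(_trial(shuffled))
        assert a.max_abs_is_mm == b.max_abs_is_mm
        assert a.max_abs_ap_mm == b.max_abs_ap_mm

    def test_mean_of_per_cycle_maxima(self):
        frames = ([_frame_result(t, 0, [0, 1.0e-3, 0]) for t in (0, 1, 2, 3)]
                  + [_frame_result(t, 0, [0, 2.0e-3, 0]) for t in (4.5, 5, 6, 7)])
        s = summarize_translations(_trial(frames, n_cycles=2))
        assert s.per_cycle_is_mm == pytest.approx([1.0, 2.0])
        assert s.max_abs_is_mm == pytest.approx(1.5)

    def test_unconverged_frames_excluded(self):
        frames = [_frame_result(0, 0, [0, 1.0e-3, 0]),
                  _frame_result(1, 0, [0, 9.0e-3, 0], converged=False)]
        s = summarize_translations(_trial(frames))
        assert s.max_abs_is_mm == pytest.approx(1.0)
        assert s.n_converged == 1

    def test_no_converged_frames_raises(self):
        frames = [_frame_result(0, 0, [0, 0, 0], converged=False)]
        with pytest.raises(EmptySummaryError):
            summarize_translations(_trial(frames))

    def test_synthetic_fluoro_amplitude_recovered(self):
        from glenofdk.fixtures import synth_fluoro_translations

        prof = make_motion(peak=30, n_cycles=3, frame_rate=5.0)
        series = synth_fluoro_translations(prof, amplitude=1.4, noise_sd=0.0)
        assert max_abs_is(series) == pytest.approx(1.4)


class TestCompareModels:
    def test_identical_trials_zero_difference(self, fixture0):
        frames = [_frame_result(t, 10.0 * t, [0, 0, 0], reaction=(5.0, -8.0, -120.0))
                  for t in (0, 1, 2)]
        fdk = _trial(list(frames), mode="fdk")
        default = _trial(list(frames), mode="default")
        cmp = compare_models(fdk, default, fixture0)
        assert np.allclose(cmp["muscles"]["diff_n"], 0.0)
        assert cmp["reaction_diff"]["compressive_n"] == 0.0
        assert cmp["translations_default_mm"]["is"] == 0.0

    def test_mode_mismatch_rejected(self, fixture0):
        frames = [_frame_result(0, 0, [0, 0, 0])]
        with pytest.raises(ValueError):
            compare_models(_trial(frames, mode="default"), _trial(frames, mode="default"),
                           fixture0)

    def test_loadcase_mismatch_rejected(self, fixture0):
        frames = [_frame_result(0, 0, [0, 0, 0])]
        with pytest.raises(ValueError):
            compare_models(_trial(frames, mode="fdk", mass=0.0),
                           _trial(frames, mode="default", mass=2.0), fixture0)


class TestExport:
    def test_round_trip_frame_table(self, fixture0, tmp_path):
        frames = [_frame_result(t, 5.0 * t, [1e-4 * t, -2e-4 * t, 0],
                                reaction=(1.0, 2.0, -50.0)) for t in range(4)]
        trial = _trial(frames)
        export_results([("demo", trial)], fixture0, tmp_path, seed=3)
        back = pd.read_csv(tmp_path / "demo_frames.csv")
        table = trial_to_frame_table(trial, fixture0)
        assert list(back.columns) == list(table.columns)
        num = table.select_dtypes("number")
        assert np.allclose(back[num.columns], num, atol=1e-12)

    def test_manifest_hash_reproducible(self, fixture0, tmp_path):
        frames = [_frame_result(0, 0, [0, 0, 0])]
        m1 = export_results([("a", _trial(frames))], fixture0, tmp_path / "r1", seed=3)
        m2 = export_results([("a", _trial(frames))], fixture0, tmp_path / "r2", seed=3)
        assert m1["config_hash"] == m2["config_hash"]

    def test_empty_trial_list_manifest_only(self, fixture0, tmp_path):
        export_results([], fixture0, tmp_path, seed=0)
        files = sorted(p.name for p in tmp_path.iterdir())
        assert files == ["manifest.json"]
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["trials"] == []
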