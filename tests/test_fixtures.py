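"""Synthetic-fixture generators: counts, determinism, motion, loads, fluoro."""

import numpy as np
import pytest

import glenofdk as g
from glenofdk.fixtures import (
    AnthropometricSpec,
    FixtureValidationError,
    TearSpec,
    export_fixture,
    load_fixture,
    make_fixture,
    make_loadcases,
    make_motion,
    synth_fluoro_translations,
)


class TestMakeFixture:
    def test_default_counts(self, fixture0):
        assert len(fixture0.muscle_names) == 16
        assert fixture0.n_muscle_elements == 118
        assert fixture0.ligament_spring_counts == {
            "superior_gh": 2, "middle_gh": 2, "inferior_gh": 8, "coracohumeral": 5}
        assert sum(b.n_springs for b in fixture0.ligaments) == 17

    def test_same_seed_identical(self):
        a = make_fixture(seed=7)
        b = make_fixture(seed=7)
        assert a.fingerprint() == b.fingerprint()

    def test_different_seed_differs(self):
        assert make_fixture(seed=1).fingerprint() != make_fixture(seed=2).fingerprint()

    def test_invalid_spec_names_field(self):
        with pytest.raises(FixtureValidationError, match="glenoid_radius"):
            AnthropometricSpec(glenoid_radius=0.020, humeral_head_radius=0.025)
        with pytest.raises(FixtureValidationError, match="body_mass"):
            AnthropometricSpec(body_mass=-5)
        with pytest.raises(FixtureValidationError, match="glenoid_cap_half_angle"):
            AnthropometricSpec(glenoid_cap_half_angle=95.0)

    def test_neutral_clearance_equals_gap(self):
        fx = make_fixture(seed=0)
        spec = fx.anthropometrics
        # deepest glenoid point sits `gap` below the head surface
        C_g = np.array([0, 0, spec.glenoid_radius * np.cos(np.deg2rad(35.0))])
        deepest = C_g - [0, 0, spec.glenoid_radius]
        clearance = (np.linalg.norm(fx.head_center - deepest) - fx.head_radius)
        assert clearance == pytest.approx(fx.initial_gap, abs=1e-12)

    def test_meshes_well_formed(self, fixture0):
        for mesh in (fixture0.glenoid_mesh, fixture0.labrum_mesh,
                     fixture0.humeral_head_mesh):
            assert mesh.is_winding_consistent
            assert np.all(mesh.area_faces > 0)

    def test_tear_factors_propagate(self):
        fx = make_fixture(tear=TearSpec(supraspinatus=0.5, infraspinatus=0.0))
        factors = {e.muscle: e.tear_factor for e in fx.muscles}
        assert factors["supraspinatus"] == 0.5
        assert factors["infraspinatus"] == 0.0
        assert factors["deltoid_lateral"] == 1.0

    def test_invalid_tear_level_rejected(self):
        with pytest.raises(FixtureValidationError):
            TearSpec(supraspinatus=0.7)

    def test_export_import_round_trip(self, fixture0, tmp_path):
        export_fixture(fixture0, tmp_path)
        back = load_fixture(tmp_path)
        assert back.n_muscle_elements == 118
        assert np.allclose(back.head_center, fixture0.head_center)
        for a, b in zip(fixture0.muscles, back.muscles):
            assert a.muscle == b.muscle
            assert np.allclose(a.origin, b.origin)
            assert a.l_opt == pytest.approx(b.l_opt)
        for a, b in zip(fixture0.ligaments, back.ligaments):
            assert np.allclose(a.slack_lengths, b.slack_lengths)
        assert np.allclose(back.glenoid_mesh.vertices, fixture0.glenoid_mesh.vertices,
                           atol=1e-7)


class TestMakeMotion:
    def test_three_cycles_three_peaks(self):
        prof = make_motion(peak=30, n_cycles=3, frame_rate=5.0)
        elev = prof.elevations
        assert np.sum(np.isclose(elev, 30.0)) == 3
        assert elev.min() == 0.0
        assert elev[0] == 0.0 and elev[-1] == 0.0

    def test_single_cycle_symmetric_ramp(self):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=10.0)
        elev = prof.elevations
        assert np.allclose(elev, elev[::-1], atol=1e-9)
        assert np.sum(np.isclose(elev, 30.0)) == 1

    def test_each_cycle_monotone_up_then_down(self):
        prof = make_motion(peak=30, n_cycles=2, frame_rate=5.0, cycle_duration=4.0)
        t = prof.times
        elev = prof.elevations
        for c in range(2):
            up = elev[(t >= c * 4.0) & (t <= c * 4.0 + 2.0)]
            down = elev[(t >= c * 4.0 + 2.0) & (t <= (c + 1) * 4.0)]
            assert np.all(np.diff(up) > -1e-12)
            assert np.all(np.diff(down) < 1e-12)

    def test_profile_continuously_differentiable(self):
        prof = make_motion(peak=30, n_cycles=2, frame_rate=5.0, cycle_duration=4.0)
        h = 1e-6
        for t in (3.999999, 4.0, 2.0, 6.0):  # cycle boundary and peaks
            d1 = (prof.elevation_at(t) - prof.elevation_at(t - h)) / h
            d2 = (prof.elevation_at(t + h) - prof.elevation_at(t)) / h
            assert abs(d1 - d2) < 1e-3  # slope continuous (rate deg/s scale)

    @pytest.mark.parametrize("kwargs", [
        {"peak": 0}, {"peak": 200}, {"n_cycles": 0}, {"frame_rate": 0.0},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            make_motion(**{"peak": 30, "n_cycles": 1, "frame_rate": 5.0, **kwargs})


class TestLoadCases:
    def test_battery_masses(self):
        cases = make_loadcases()
        assert [c.handheld_mass for c in cases] == [0.0, 1.0, 2.0, 3.0]
        assert all(c.gravity == 9.81 for c in cases)
        offsets = {c.hand_offset for c in cases}
        assert len(offsets) == 1  # only the mass varies


class TestSynthFluoro:
    def test_noise_free_amplitude(self):
        prof = make_motion(peak=30, n_cycles=3, frame_rate=10.0)
        df = synth_fluoro_translations(prof, amplitude=1.4, noise_sd=0.0)
        assert df["is_mm"].abs().max() == pytest.approx(1.4)
        assert list(df.columns) == ["time_s", "ap_mm", "is_mm"]

    def test_zero_amplitude_zero_series(self):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=5.0)
        df = synth_fluoro_translations(prof, amplitude=0.0, noise_sd=0.0)
        assert np.allclose(df[["ap_mm", "is_mm"]], 0.0)

    def test_seeds_differ_envelope_shared(self):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=5.0)
        a = synth_fluoro_translations(prof, 1.4, 0.3, seed=1)
        b = synth_fluoro_translations(prof, 1.4, 0.3, seed=2)
        clean = synth_fluoro_translations(prof, 1.4, 0.0)
        assert not np.allclose(a["is_mm"], b["is_mm"])
        # noise-free envelope: the mean of many draws approaches the clean curve
        draws = np.stack([synth_fluoro_translations(prof, 1.4, 0.3, seed=s)["is_mm"]
                          for s in range(200)])
        assert np.allclose(draws.mean(axis=0), clean["is_mm"], atol=0.1)

    def test_reproducible_by_seed(self):
        prof = make_motion(peak=30, n_cycles=1, frame_rate=5.0)
        a = synth_fluoro_translations(prof, 1.4, 0.3, seed=9)
        b = synth_fluoro_translations(prof, 1.4, 0.3, seed=9)
        assert a.equals(b)
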