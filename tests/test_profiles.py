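"""Ray-traced profiles, edge metrics, calibration, fixtures."""

import math

import numpy as np
import pytest

from cimlc import (
    BeamlineGeometry,
    CalibrationRangeError,
    DoseProfile,
    EdgeNotFoundError,
    LeafSetting,
    ValidationError,
    apply_calibration,
    extract_edge_metrics,
    fit_calibration,
    generate_fixture_profiles,
    read_profile_csv,
    solve_x_p,
    trace_profile,
    write_profile_csv,
)


class TestTraceProfile:
    def test_open_field_is_unity(self, geom, tungsten):
        s = LeafSetting(6.0)
        prof = trace_profile(s, tungsten, geom, np.linspace(0.0, 5.0, 20))
        assert np.allclose(prof.doses, 1.0)

    def test_full_shadow_transmission(self, geom, tungsten):
        # deep under the leaf every ray crosses the full slant thickness
        positions = np.linspace(8.0, 8.5, 8)
        prof = trace_profile(LeafSetting(6.0), tungsten, geom, positions)
        t = math.atan(8.0 / geom.sad_cm)
        assert prof.doses[0] == pytest.approx(math.exp(-6.24 / (2.7 * math.cos(t))), rel=1e-12)
        assert prof.doses[0] == pytest.approx(0.099, abs=1e-3)

    def test_monotone_nonincreasing_across_edge(self, geom, materials):
        for m in materials.values():
            prof = trace_profile(LeafSetting(5.0), m, geom, np.arange(4.0, 7.0, 0.005))
            assert np.all(np.diff(prof.doses) <= 1e-15)

    def test_traced_50pct_crossing_matches_chord_solve(self, geom, tungsten):
        s = LeafSetting(9.0)
        prof = trace_profile(s, tungsten, geom, np.arange(8.7, 9.6, 0.001))
        metrics = extract_edge_metrics(prof)
        assert metrics.x50_cm == pytest.approx(solve_x_p(s, tungsten, geom, 0.5), abs=1e-4)

    def test_mirrored_setting_traces_mirrored_profile(self, geom, tungsten):
        pos = np.arange(5.5, 6.5, 0.01)
        right = trace_profile(LeafSetting(6.0, 1), tungsten, geom, pos)
        left = trace_profile(LeafSetting(6.0, -1), tungsten, geom, -pos[::-1])
        assert np.allclose(right.doses, left.doses[::-1])


class TestExtractEdgeMetrics:
    def test_analytic_ramp(self):
        # step at a with a linear ramp of width w: x50 = a + w/2, penumbra = 0.6*w
        a, w = 3.0, 0.4
        pos = np.linspace(2.0, 4.5, 501)
        dose = np.clip(1.0 - (pos - a) / w, 0.0, 1.0)
        metrics = extract_edge_metrics(DoseProfile(pos, dose, central_axis_dose=1.0))
        assert metrics.x50_cm == pytest.approx(a + w / 2, abs=1e-9)
        assert metrics.x20_cm == pytest.approx(a + 0.8 * w, abs=1e-9)
        assert metrics.x80_cm == pytest.approx(a + 0.2 * w, abs=1e-9)
        assert metrics.penumbra_mm == pytest.approx(0.6 * w * 10, abs=1e-7)

    def test_traced_penumbra_matches_model(self, geom, tungsten):
        from cimlc import model_penumbra

        s = LeafSetting(6.0)
        prof = trace_profile(s, tungsten, geom, np.arange(5.7, 6.5, 0.001))
        metrics = extract_edge_metrics(prof)
        assert metrics.penumbra_mm == pytest.approx(model_penumbra(s, tungsten, geom), abs=2e-3)
        assert metrics.penumbra_mm == pytest.approx(1.17, abs=0.01)

    def test_grid_refinement_converges(self, geom, tungsten):
        s = LeafSetting(6.0)
        truth = solve_x_p(s, tungsten, geom, 0.5)
        errs = []
        for step in (0.02, 0.002):
            prof = trace_profile(s, tungsten, geom, np.arange(5.7, 6.5, step))
            errs.append(abs(extract_edge_metrics(prof).x50_cm - truth))
        assert errs[1] < errs[0] or errs[1] < 1e-6

    def test_constant_profile_has_no_edge(self):
        prof = DoseProfile(np.linspace(0, 1, 16), np.full(16, 0.9), central_axis_dose=1.0)
        with pytest.raises(EdgeNotFoundError):
            extract_edge_metrics(prof)

    def test_multiple_crossings_use_outermost_with_warning(self):
        pos = np.linspace(0.0, 3.0, 301)
        dose = np.where(pos < 1.0, 1.0, np.where(pos < 1.5, 0.1, np.where(pos < 2.0, 0.9, 0.0)))
        # smooth the steps so every level is crossed by interpolation
        prof = DoseProfile(pos, dose, central_axis_dose=1.0)
        with pytest.warns(UserWarning, match="outermost"):
            metrics = extract_edge_metrics(prof)
        assert metrics.x50_cm > 1.9

    def test_profile_validation(self):
        with pytest.raises(ValidationError):
            DoseProfile(np.array([0, 1, 2]), np.array([1, 1, 1]))  # too few samples
        with pytest.raises(ValidationError):
            DoseProfile(np.linspace(1, 0, 16), np.ones(16), central_axis_dose=1.0)
        with pytest.raises(ValidationError):
            DoseProfile(np.linspace(0, 1, 16), -np.ones(16), central_axis_dose=1.0)


class TestCalibration:
    def test_knot_round_trip(self):
        curve = fit_calibration([5, 100, 200], [0.1, 0.8, 1.2])
        assert apply_calibration(curve, 0.8) == pytest.approx(100.0)
        for d, r in zip(curve.doses_cGy, curve.responses):
            assert apply_calibration(curve, r) == pytest.approx(d)

    def test_monotone_between_knots(self):
        curve = fit_calibration([5, 100, 200], [0.1, 0.8, 1.2])
        queries = np.linspace(0.1, 1.2, 50)
        doses = apply_calibration(curve, queries)
        assert np.all(np.diff(doses) > 0)

    def test_collinear_knot_is_redundant(self):
        curve3 = fit_calibration([10.0, 20.0, 30.0], [1.0, 2.0, 3.0])
        curve4 = fit_calibration([10.0, 20.0, 25.0, 30.0], [1.0, 2.0, 2.5, 3.0])
        q = np.linspace(1.0, 3.0, 40)
        assert np.allclose(apply_calibration(curve3, q), apply_calibration(curve4, q))

    def test_saturating_film_response_round_trip(self):
        # synthetic H-D curve d = 250*(1 - e^-r) sampled at the nine graded doses
        doses = np.array([5, 10, 15, 40, 60, 80, 100, 150, 200], dtype=float)
        responses = -np.log(1 - doses / 250.0)
        curve = fit_calibration(doses, responses)
        mid = (responses[:-1] + responses[1:]) / 2
        recovered = apply_calibration(curve, mid)
        truth = 250.0 * (1 - np.exp(-mid))
        assert np.all(np.abs(recovered - truth) / truth < 0.02)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration([5, 100, 200], [0.1, 0.9, 0.8])

    def test_extrapolation_rejected(self):
        curve = fit_calibration([5, 100, 200], [0.1, 0.8, 1.2])
        with pytest.raises(CalibrationRangeError):
            apply_calibration(curve, 1.5)


class TestFixtures:
    def test_seeded_generation_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_fixture_profiles(seed=1, n_cases=3, out_dir=d1)
        generate_fixture_profiles(seed=1, n_cases=3, out_dir=d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_noiseless_fixture_recovers_truth(self, tmp_path):
        manifest = generate_fixture_profiles(seed=7, n_cases=4, out_dir=tmp_path)
        for case in manifest["cases"]:
            prof = read_profile_csv(tmp_path / case["file"])
            metrics = extract_edge_metrics(prof)
            assert metrics.x50_cm == pytest.approx(case["true_x50_cm"], abs=1e-4)
            assert metrics.penumbra_mm == pytest.approx(case["true_penumbra_mm"], abs=2e-3)

    def test_noisy_fixture_recovers_x50_within_tolerance(self, tmp_path):
        manifest = generate_fixture_profiles(seed=11, n_cases=4, out_dir=tmp_path, noise_sigma=0.005)
        for case in manifest["cases"]:
            prof = read_profile_csv(tmp_path / case["file"])
            metrics = extract_edge_metrics(prof)
            assert metrics.x50_cm == pytest.approx(case["true_x50_cm"], abs=0.02)

    def test_profile_csv_round_trip(self, tmp_path, geom, tungsten):
        prof = trace_profile(LeafSetting(4.0), tungsten, geom, np.arange(3.5, 4.5, 0.01))
        path = tmp_path / "p.csv"
        write_profile_csv(path, prof)
        back = read_profile_csv(path)
        assert np.allclose(back.positions_cm, prof.positions_cm, atol=1e-6)
        assert np.allclose(back.doses, prof.doses, rtol=1e-8)
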