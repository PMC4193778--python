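"""Shell measurement, altitude scaling, ground-truth calibration,
frame filtering/sampling and dead-shell exclusion."""

import numpy as np
import pandas as pd
import pytest

from scallopsize import measurement as meas
from scallopsize import simulate as sim
from scallopsize.calibration import DistortionCorrectionModel
from scallopsize.errors import (
    ExcludedRecordError,
    InvalidGeometryError,
    JoinError,
    UnderdeterminedFitError,
)

IDENTITY = DistortionCorrectionModel.identity()


def ann(tip=(0, 0), base=(3, 4), partial=False):
    return {
        "shell_id": "sh1", "image_id": "img1",
        "tip_x_px": tip[0], "tip_y_px": tip[1],
        "base_x_px": base[0], "base_y_px": base[1],
        "status": "live", "partially_visible": partial,
    }


class TestMeasureShell:
    def test_pythagorean_span_at_equal_altitudes(self):
        # identity model maps px to cm one-to-one; 3-4-5 triangle
        h = meas.measure_shell(ann(), {"altitude_m": 2.0}, IDENTITY, 2.0)
        assert h == pytest.approx(5.0, rel=1e-12)

    def test_altitude_scaling_is_linear(self):
        h = meas.measure_shell(ann(), {"altitude_m": 4.0}, IDENTITY, 2.0)
        assert h == pytest.approx(10.0, rel=1e-12)

    def test_scaling_homogeneity(self):
        base = meas.measure_shell(ann(), {"altitude_m": 1.7}, IDENTITY, 2.0)
        for k in (0.5, 2.0, 3.3):
            scaled = meas.measure_shell(
                ann(), {"altitude_m": 1.7 * k}, IDENTITY, 2.0
            )
            assert scaled == pytest.approx(k * base, rel=1e-12)

    def test_degenerate_and_excluded_annotations(self):
        with pytest.raises(InvalidGeometryError):
            meas.measure_shell(ann(tip=(3, 4)), {"altitude_m": 2.0},
                               IDENTITY, 2.0)
        with pytest.raises(ExcludedRecordError):
            meas.measure_shell(ann(partial=True), {"altitude_m": 2.0},
                               IDENTITY, 2.0)
        with pytest.raises(InvalidGeometryError):
            meas.measure_shell(ann(), {"altitude_m": 0.0}, IDENTITY, 2.0)

    def test_missing_metadata_join_fails(self):
        annotations = pd.DataFrame([ann()])
        metadata = pd.DataFrame(
            [{"image_id": "other", "survey_id": "s1", "transect_id": "t1",
              "altitude_m": 2.0}]
        )
        with pytest.raises(JoinError):
            meas.measure_shells(annotations, metadata, IDENTITY, 2.0)


class TestSizeCalibration:
    def test_identity_when_estimates_equal_known(self):
        known = [5.5, 6.0, 6.5, 7.0]
        cal = meas.fit_size_calibration(known, known)
        assert cal.slope == pytest.approx(1.0, abs=1e-10)
        assert cal.intercept_cm == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_recovered(self):
        known = np.array([5.5, 6.0, 6.5, 7.0])
        cal = meas.fit_size_calibration(known, known - 0.5)
        assert cal.slope == pytest.approx(1.0, abs=1e-10)
        assert cal.intercept_cm == pytest.approx(0.5, abs=1e-10)

    def test_underdetermined_inputs(self):
        with pytest.raises(UnderdeterminedFitError):
            meas.fit_size_calibration([6.0], [5.5])
        with pytest.raises(UnderdeterminedFitError):
            meas.fit_size_calibration([5.0, 6.0], [5.5, 5.5])

    def test_apply_is_affine_and_monotone(self):
        cal = meas.SizeCalibration(slope=1.0, intercept_cm=0.5,
                                   n_categories=4)
        assert meas.apply_calibration(cal, 6.0) == pytest.approx(6.5)
        ident = meas.SizeCalibration.identity()
        assert meas.apply_calibration(ident, 6.2) == pytest.approx(6.2)
        a, b = meas.apply_calibration(cal, np.array([5.0, 7.0]))
        assert a < b

    def test_residuals_sum_to_zero(self):
        known = [5.4, 6.1, 6.6, 6.9]
        est = [5.0, 5.6, 6.2, 6.5]
        cal = meas.fit_size_calibration(known, est)
        fitted = meas.apply_calibration(cal, np.array(est))
        assert float(np.sum(np.array(known) - fitted)) == pytest.approx(
            0.0, abs=1e-10
        )


def meta_rows(altitudes, survey="s1", transect="t1"):
    return pd.DataFrame(
        [
            {"image_id": f"{survey}_{transect}_f{i}", "survey_id": survey,
             "transect_id": transect, "altitude_m": a}
            for i, a in enumerate(altitudes)
        ]
    )


class TestFrameFiltering:
    def test_window_retains_in_range_only(self):
        md = meta_rows([1.96, 2.6, 1.4])
        retained, retention = meas.filter_frames(md, (1.5, 2.5))
        assert retained["altitude_m"].tolist() == [1.96]
        assert retention["retention_pct"].iloc[0] == pytest.approx(100 / 3)

    def test_window_covering_all_gives_full_retention(self):
        md = pd.concat(
            [meta_rows([1.8, 2.0], transect="t1"),
             meta_rows([2.2, 2.4], transect="t2")],
            ignore_index=True,
        )
        _, retention = meas.filter_frames(md, (0.5, 5.0))
        assert (retention["retention_pct"] == 100.0).all()

    def test_constructed_forty_percent_retention(self):
        alts = [2.0] * 40 + [3.0] * 60
        _, retention = meas.filter_frames(meta_rows(alts), (1.5, 2.5))
        assert retention["retention_pct"].iloc[0] == pytest.approx(40.0)

    def test_invalid_window(self):
        with pytest.raises(InvalidGeometryError):
            meas.filter_frames(meta_rows([2.0]), (2.5, 1.5))

    def test_empty_input_gives_empty_output(self):
        empty = meta_rows([]).iloc[0:0]
        retained, retention = meas.filter_frames(empty, (1.5, 2.5))
        assert retained.empty and retention.empty


class TestFrameSampling:
    def test_exact_sample_size_and_determinism(self):
        md = meta_rows(np.linspace(1.6, 2.4, 100))
        s1 = meas.sample_frames(md, 25, seed=9)
        s2 = meas.sample_frames(md, 25, seed=9)
        assert len(s1) == 25
        assert s1["image_id"].nunique() == 25
        assert s1["image_id"].tolist() == s2["image_id"].tolist()
        s3 = meas.sample_frames(md, 25, seed=10)
        assert s3["image_id"].tolist() != s1["image_id"].tolist()

    def test_undersized_transect_returns_all(self, caplog):
        md = meta_rows([2.0] * 10)
        out = meas.sample_frames(md, 25, seed=0)
        assert len(out) == 10


class TestExcludeDead:
    def test_mixed_statuses(self):
        df = pd.DataFrame({"status": ["live"] * 7 + ["dead"] * 3})
        assert len(meas.exclude_dead(df)) == 7

    def test_all_live_identity_and_all_dead_empty(self):
        live = pd.DataFrame({"status": ["live"] * 4})
        assert len(meas.exclude_dead(live)) == 4
        dead = pd.DataFrame({"status": ["dead"] * 4})
        assert meas.exclude_dead(dead).empty


class TestQuantizationError:
    def test_mean_abs_error_bounded_by_two_pixels_worth(self):
        """Rounding endpoints to integer pixels costs at most about one
        ground-sample distance per endpoint on average."""
        cam = sim.TrueCameraModel()
        pop = sim.PopulationSpec()
        plan = sim.SurveyPlan(n_surveys=1, transects_per_survey=2,
                              frames_per_transect_available=120,
                              altitude_sd_m=0.0)
        md, ann_df, truth = sim.generate_survey_data(
            pop, plan, cam, 2.0, sigma_transect=0, sigma_frame=0,
            quantize=True, drop_partial=True, seed=21,
        )
        m = meas.measure_shells(ann_df, md, IDENTITY_CM_MODEL(cam), 2.0)
        j = m.merge(truth, on="shell_id")
        assert len(j) >= 500
        gsd = cam.ground_sample_distance_cm(2.0)[0]
        mae = float(np.abs(j.raw_height_cm - j.true_height_cm).mean())
        assert mae <= 2.0 * gsd

    def test_calibration_removes_constant_bias(self):
        """A constant -0.5 cm bias injected into ground-truth estimates
        is removed by the 4-category-mean calibration."""
        cam = sim.TrueCameraModel()
        ann_df, md, known = sim.generate_ground_truth_experiment(
            cam, quantize=True, seed=5
        )
        m = meas.measure_shells(ann_df, md, IDENTITY_CM_MODEL(cam), 2.0)
        j = m.merge(known, on="shell_id")
        j["biased_cm"] = j["raw_height_cm"] - 0.5
        by_cat = j.groupby("category").agg(
            known=("known_height_cm", "mean"), est=("biased_cm", "mean")
        )
        cal = meas.fit_size_calibration(by_cat["known"], by_cat["est"])
        corrected = meas.apply_calibration(cal, j["biased_cm"])
        err = corrected - j["known_height_cm"]
        se = float(err.std(ddof=1)) / np.sqrt(len(err))
        assert abs(float(err.mean())) <= 3 * se


def IDENTITY_CM_MODEL(camera, h=2.0):
    """Exact linear correction for a distortion-free camera: pixel ->
    cm in the plane at altitude h (used as a noiseless lens model)."""
    gx, gy = camera.ground_sample_distance_cm(h)
    cx = camera.image_width_px / 2.0
    cy = camera.image_height_px / 2.0
    return DistortionCorrectionModel(
        coeffs_x=[-cx * gx, gx, 0, 0, 0, 0],
        coeffs_y=[0 - cy * gy, 0, gy, 0, 0, 0],
        fit_rmse_x=0.0, fit_rmse_y=0.0, n_points=0, frame_altitude_m=h,
    )
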