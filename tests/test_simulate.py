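"""Synthetic camera/population/survey generator properties."""

import numpy as np
import pytest

from scallopsize import calibration as cal
from scallopsize import measurement as meas
from scallopsize import simulate as sim


class TestCameraModel:
    def test_identity_projection_round_trips_scale(self, identity_camera):
        cam = identity_camera
        pts_m = np.array([[0.0, 0.0], [0.3, -0.2]])
        px = cam.project_ground(pts_m, altitude_m=2.0)
        # center maps to sensor center
        np.testing.assert_allclose(
            px[0], [cam.image_width_px / 2, cam.image_height_px / 2]
        )
        gx, gy = cam.ground_sample_distance_cm(2.0)
        np.testing.assert_allclose(
            px[1] - px[0], [30.0 / gx, -20.0 / gy], rtol=1e-12
        )

    def test_footprint_near_design_target(self, identity_camera):
        fx, fy = identity_camera.footprint_m(2.0)
        assert fx == pytest.approx(2.0, abs=0.01)
        assert fy == pytest.approx(1.2, abs=0.01)

    def test_pincushion_is_injective_but_strong_twist_is_not(self):
        assert sim.TrueCameraModel.with_pincushion(0.05).check_injective()
        assert not sim.TrueCameraModel.with_pincushion(0.8).check_injective()


class TestCalibrationGrid:
    def test_identity_camera_distorted_equals_scaled_reference(
        self, identity_camera
    ):
        grid = sim.generate_calibration_grid(identity_camera, noise_sd_px=0)
        gx, gy = identity_camera.ground_sample_distance_cm(2.0)
        cx = identity_camera.image_width_px / 2
        cy = identity_camera.image_height_px / 2
        np.testing.assert_allclose(
            grid.distorted_points[:, 0],
            cx + grid.reference_points[:, 0] / gx, atol=1e-9,
        )
        np.testing.assert_allclose(
            grid.distorted_points[:, 1],
            cy + grid.reference_points[:, 1] / gy, atol=1e-9,
        )

    def test_explicit_node_counts(self, identity_camera):
        grid = sim.generate_calibration_grid(
            identity_camera, n_cols=10, n_rows=8
        )
        assert grid.n_points == 80
        assert grid.grid_spacing_cm == 15.0

    def test_reference_nodes_on_spacing_lattice(self, pincushion_camera):
        grid = sim.generate_calibration_grid(pincushion_camera)
        diffs = np.diff(np.unique(np.round(grid.reference_points[:, 0], 9)))
        np.testing.assert_allclose(diffs, 15.0)

    def test_correction_fit_round_trips_nodes(self, pincushion_camera):
        """Forward-then-correction returns reference nodes within the
        inverse-approximation budget (exact only if the true inverse
        were itself quadratic)."""
        grid = sim.generate_calibration_grid(pincushion_camera, noise_sd_px=0)
        model = cal.fit_distortion_model(grid)
        pred = model.predict(grid.distorted_points)
        assert np.max(np.abs(pred - grid.reference_points)) <= 0.05

    def test_reproducible_under_seed(self, pincushion_camera):
        g1 = sim.generate_calibration_grid(pincushion_camera, noise_sd_px=0.5,
                                           seed=3)
        g2 = sim.generate_calibration_grid(pincushion_camera, noise_sd_px=0.5,
                                           seed=3)
        np.testing.assert_array_equal(g1.distorted_points,
                                      g2.distorted_points)


class TestSurveyData:
    def test_identity_pipeline_recovers_true_heights(self, identity_camera):
        from test_measurement import IDENTITY_CM_MODEL

        plan = sim.SurveyPlan(n_surveys=1, transects_per_survey=1,
                              frames_per_transect_available=20,
                              altitude_sd_m=0.0)
        md, ann, truth = sim.generate_survey_data(
            sim.PopulationSpec(), plan, identity_camera, 2.0,
            sigma_transect=0, sigma_frame=0, quantize=False, seed=9,
        )
        m = meas.measure_shells(ann, md, IDENTITY_CM_MODEL(identity_camera),
                                2.0)
        j = m.merge(truth, on="shell_id")
        rel = np.abs(j.raw_height_cm - j.true_height_cm) / j.true_height_cm
        assert len(j) > 10
        assert rel.max() < 1e-9

    def test_plan_defaults_produce_joinable_hierarchy(self, identity_camera):
        plan = sim.SurveyPlan(frames_per_transect_available=2)
        md, ann, truth = sim.generate_survey_data(
            sim.PopulationSpec(), plan, identity_camera, seed=1
        )
        assert len(md) == 5 * 4 * 2
        assert md["survey_id"].nunique() == 5
        assert md.groupby("survey_id")["transect_id"].nunique().eq(4).all()
        # no orphan annotations, truth aligned with annotations
        assert set(ann["image_id"]) <= set(md["image_id"])
        assert set(ann["shell_id"]) == set(truth["shell_id"])
        assert md["image_id"].is_unique and ann["shell_id"].is_unique

    def test_poisson_shell_counts_match_density_times_area(
        self, identity_camera
    ):
        plan = sim.SurveyPlan(n_surveys=1, transects_per_survey=1,
                              frames_per_transect_available=1000,
                              altitude_mean_m=2.0, altitude_sd_m=0.0)
        md, ann, _ = sim.generate_survey_data(
            sim.PopulationSpec(density_per_m2=1.0), plan, identity_camera,
            seed=17,
        )
        fx, fy = identity_camera.footprint_m(2.0)
        mean_per_frame = len(ann) / len(md)
        assert fx * fy == pytest.approx(2.4, abs=0.05)
        assert 2.0 <= mean_per_frame <= 2.9

    def test_bitwise_reproducibility(self, identity_camera):
        args = (sim.PopulationSpec(), sim.SurveyPlan(
            n_surveys=2, frames_per_transect_available=5), identity_camera)
        out1 = sim.generate_survey_data(*args, seed=33)
        out2 = sim.generate_survey_data(*args, seed=33)
        for a, b in zip(out1, out2):
            assert a.equals(b)

    def test_out_of_frame_shells_flagged_or_dropped(self, identity_camera):
        plan = sim.SurveyPlan(n_surveys=1, transects_per_survey=1,
                              frames_per_transect_available=200)
        _, ann_keep, _ = sim.generate_survey_data(
            sim.PopulationSpec(), plan, identity_camera, seed=2,
            drop_partial=False,
        )
        _, ann_drop, _ = sim.generate_survey_data(
            sim.PopulationSpec(), plan, identity_camera, seed=2,
            drop_partial=True,
        )
        assert ann_keep["partially_visible"].any()
        assert not ann_drop["partially_visible"].any()
        assert len(ann_drop) == (~ann_keep["partially_visible"]).sum()


class TestGroundTruthExperiment:
    def test_quantization_off_recovers_known_means_exactly(
        self, identity_camera
    ):
        from test_measurement import IDENTITY_CM_MODEL

        ann, md, known = sim.generate_ground_truth_experiment(
            identity_camera, quantize=False, seed=4
        )
        m = meas.measure_shells(ann, md, IDENTITY_CM_MODEL(identity_camera),
                                2.0)
        j = m.merge(known, on="shell_id")
        per_cat = j.groupby("category").agg(
            known=("known_height_cm", "mean"), est=("raw_height_cm", "mean")
        )
        np.testing.assert_allclose(per_cat["est"], per_cat["known"],
                                   rtol=1e-9)

    def test_quantized_bias_bounded_by_pixel_size(self, identity_camera):
        from test_measurement import IDENTITY_CM_MODEL

        ann, md, known = sim.generate_ground_truth_experiment(
            identity_camera, n_per_category=50, quantize=True, seed=6
        )
        m = meas.measure_shells(ann, md, IDENTITY_CM_MODEL(identity_camera),
                                2.0)
        j = m.merge(known, on="shell_id")
        g = identity_camera.ground_sample_distance_cm(2.0)[0]
        bias = (j.groupby("category")
                .apply(lambda x: (x.raw_height_cm - x.known_height_cm).mean(),
                       include_groups=False))
        assert np.all(np.abs(bias) <= 2 * g)

    def test_adjacent_half_centimeter_categories_separable(
        self, identity_camera
    ):
        """Estimated means of categories 0.5 cm apart stay ordered in
        nearly every replicate despite pixel quantization."""
        from test_measurement import IDENTITY_CM_MODEL

        model = IDENTITY_CM_MODEL(identity_camera)
        ordered = 0
        n_rep = 50
        for rep in range(n_rep):
            ann, md, known = sim.generate_ground_truth_experiment(
                identity_camera, category_means_cm=(6.0, 6.5),
                n_per_category=25, quantize=True, seed=100 + rep,
            )
            m = meas.measure_shells(ann, md, model, 2.0)
            j = m.merge(known, on="shell_id")
            means = j.groupby("category")["raw_height_cm"].mean()
            ordered += means.loc[2] > means.loc[1]
        assert ordered >= 0.95 * n_rep


class TestNestedHeightSimulator:
    def test_balanced_counts(self):
        df = sim.simulate_nested_heights(
            n_surveys=3, transects_per_survey=2, frames_per_transect=4,
            obs_per_frame=2, rng=0,
        )
        assert len(df) == 3 * 2 * 4 * 2
        sizes = df.groupby(["survey_id", "transect_id", "frame_id"]).size()
        assert (sizes == 2).all()

    def test_zero_variance_levels_are_constant(self):
        df = sim.simulate_nested_heights(
            sigma2_survey=0, sigma2_transect=0, sigma2_frame=0,
            sigma2_resid=0, n_surveys=2, transects_per_survey=2,
            frames_per_transect=2, obs_per_frame=2, rng=1,
        )
        assert (df["height_cm"] == 6.0).all()


def test_render_frame_image(tmp_path, identity_camera):
    import pandas as pd
    from PIL import Image

    ann = pd.DataFrame(
        [
            {"shell_id": "a", "image_id": "i", "tip_x_px": 300,
             "tip_y_px": 300, "base_x_px": 360, "base_y_px": 300,
             "status": "live", "partially_visible": False},
            {"shell_id": "b", "image_id": "i", "tip_x_px": 600,
             "tip_y_px": 500, "base_x_px": 650, "base_y_px": 540,
             "status": "dead", "partially_visible": False},
        ]
    )
    path = tmp_path / "frame.png"
    sim.render_frame_image(ann, identity_camera, path)
    img = np.asarray(Image.open(path))
    assert img.shape == (768, 1024)
    assert img[300, 330] == 120       # inside live shell
    assert img[520, 625] == 230       # dead shell brighter
    assert img[10, 10] == 40          # background
    # empty frame: blank sensor-sized image
    path2 = tmp_path / "empty.png"
    sim.render_frame_image(ann.iloc[0:0], identity_camera, path2)
    img2 = np.asarray(Image.open(path2))
    assert (img2 == 40).all()
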