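"""Segmentation, feature extraction and live/dead classification."""

import numpy as np
import pandas as pd
import pytest

from neuroscreen import nuclei
from neuroscreen.nuclei import (
    ClassifierModel,
    SegmentationParams,
    calibrate_classifier,
    classify_nuclei,
    extract_features,
    match_centroids,
    segment_nuclei,
)
from neuroscreen.synthetic_data import SimulationConfig, render_well_image


class TestSegmentNuclei:
    def test_blank_noise_image_yields_nothing(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(100, 20, (256, 256)), 0, 4095)
        _, records = segment_nuclei(img)
        assert len(records) == 0

    def test_constant_image_yields_nothing(self):
        _, records = segment_nuclei(np.full((128, 128), 7.0))
        assert len(records) == 0

    def test_well_separated_nuclei_all_recovered(self, sim_config):
        img, truth = render_well_image(150, 0, sim_config, seed=21)
        _, records = segment_nuclei(img)
        assert len(records) == 150
        det = records[["centroid_row", "centroid_col"]].to_numpy()
        tru = np.array([[t.row, t.col] for t in truth])
        m = match_centroids(det, tru, max_dist=2.0)
        assert m["recall"] == 1.0 and m["precision"] == 1.0

    def test_full_density_recall_precision(self, segmented_field):
        img, truth, labels, feats = segmented_field
        tru = np.array([[t.row, t.col] for t in truth])
        m = match_centroids(
            feats[["centroid_row", "centroid_col"]].to_numpy(), tru, max_dist=5.0
        )
        assert m["recall"] >= 0.95
        assert m["precision"] >= 0.95

    def test_translation_equivariance(self, sim_config):
        # small shift keeps every nucleus inside the frame, so the full set
        # of centroids must move rigidly
        img, _ = render_well_image(30, 10, sim_config, seed=3)
        _, r0 = segment_nuclei(img)
        shift = (5, 7)
        _, r1 = segment_nuclei(np.roll(img, shift, axis=(0, 1)))
        m = match_centroids(
            r1[["centroid_row", "centroid_col"]].to_numpy(),
            r0[["centroid_row", "centroid_col"]].to_numpy() + shift,
            max_dist=1.0,
        )
        assert m["recall"] >= 0.95
        for _, _, d in m["pairs"]:
            assert d <= 0.5


class TestExtractFeatures:
    def test_square_object_closed_form(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:10, 5:10] = 1
        img = np.zeros((20, 20))
        img[5:10, 5:10] = 7.0
        feats = extract_features(labels, img)
        row = feats.iloc[0]
        assert row["area"] == 25
        assert row["mean_intensity"] == pytest.approx(7.0)
        assert row["integrated_intensity"] == pytest.approx(175.0)

    def test_eccentricity_orders_circle_below_ellipse(self):
        yy, xx = np.mgrid[:60, :60]
        circle = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 100).astype(int)
        ellipse = (((yy - 30) / 3.0) ** 2 + ((xx - 30) / 9.0) ** 2 <= 1).astype(int)
        ecc_c = extract_features(circle, circle.astype(float))["eccentricity"][0]
        ecc_e = extract_features(ellipse * 1, ellipse.astype(float))["eccentricity"][0]
        assert ecc_c < ecc_e

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((4, 4), int), np.zeros((5, 5)))

    def test_dead_population_smaller_and_brighter(self, labeled_features):
        g = labeled_features.groupby("cls")[["area", "mean_intensity"]].mean()
        assert g.loc["dead", "area"] < g.loc["live", "area"]
        assert g.loc["dead", "mean_intensity"] > g.loc["live", "mean_intensity"]


def _feature_frame(area, intensity, cls):
    return pd.DataFrame(
        {
            "area": area,
            "mean_intensity": intensity,
            "integrated_intensity": np.asarray(area) * np.asarray(intensity),
            "eccentricity": 0.1,
            "cls": cls,
        }
    )


class TestCalibrateClassifier:
    def test_perfect_separation_accuracy_one(self, labeled_features):
        model = calibrate_classifier(labeled_features)
        assert model.train_accuracy >= 0.99

    def test_single_class_raises(self):
        df = _feature_frame(np.arange(40) + 30.0, np.full(40, 500.0), "live")
        with pytest.raises(ValueError, match="both classes"):
            calibrate_classifier(df)

    def test_too_few_examples_raises(self):
        df = _feature_frame(
            np.r_[np.full(30, 60.0), np.full(10, 20.0)],
            np.r_[np.full(30, 500.0), np.full(10, 2000.0)],
            ["live"] * 30 + ["dead"] * 10,
        )
        with pytest.raises(ValueError, match=">= 20"):
            calibrate_classifier(df)

    def test_deterministic(self, labeled_features):
        m1 = calibrate_classifier(labeled_features, seed=1)
        m2 = calibrate_classifier(labeled_features, seed=1)
        assert m1 == m2

    def test_matches_brute_force_grid_on_overlapping_data(self):
        """Within 2 points of the exhaustive grid optimum on noisy features."""
        rng = np.random.default_rng(42)
        n = 300
        area = np.r_[rng.normal(60, 18, n), rng.normal(35, 15, n)]
        inten = np.r_[rng.normal(600, 180, n), rng.normal(900, 250, n)]
        cls = ["live"] * n + ["dead"] * n
        df = _feature_frame(area, inten, cls)
        model = calibrate_classifier(df)

        # independent oracle: dense brute-force grid over threshold pairs
        y = np.array(cls) == "dead"
        best = 0.0
        for a in np.linspace(area.min() - 1, area.max() + 1, 150):
            small = area < a
            for i in np.linspace(inten.min() - 1, inten.max() + 1, 150):
                acc = np.mean((small & (inten > i)) == y)
                best = max(best, acc)
        assert model.train_accuracy >= best - 0.02

    def test_linear_method_trains(self, labeled_features):
        model = calibrate_classifier(labeled_features, method="linear")
        assert model.method == "linear"
        assert model.train_accuracy >= 0.95

    def test_json_round_trip(self, labeled_features, tmp_path):
        model = calibrate_classifier(labeled_features)
        model.to_json(tmp_path / "m.json")
        assert ClassifierModel.from_json(tmp_path / "m.json") == model


class TestClassifyNuclei:
    MODEL = ClassifierModel(area_threshold=40.0, intensity_threshold=1000.0)

    def test_small_bright_is_dead(self):
        df = _feature_frame([10.0], [3000.0], ["?"])
        assert classify_nuclei(df, self.MODEL)["predicted_class"][0] == "dead"

    def test_boundary_record_is_live(self):
        # strict inequalities: exactly at either threshold -> live
        df = _feature_frame([40.0, 10.0], [3000.0, 1000.0], ["?", "?"])
        out = classify_nuclei(df, self.MODEL)
        assert list(out["predicted_class"]) == ["live", "live"]

    def test_missing_feature_raises(self):
        df = pd.DataFrame({"area": [10.0]})
        with pytest.raises(ValueError, match="mean_intensity"):
            classify_nuclei(df, self.MODEL)

    def test_unused_features_do_not_matter(self, labeled_features):
        model = calibrate_classifier(labeled_features)
        base = classify_nuclei(labeled_features, model)["predicted_class"]
        perturbed = labeled_features.copy()
        perturbed["eccentricity"] = 0.99
        perturbed["integrated_intensity"] *= 17.0
        after = classify_nuclei(perturbed, model)["predicted_class"]
        assert (base == after).all()

    def test_per_well_dead_fraction_close_to_truth(self, labeled_features,
                                                   segmented_field):
        img, truth, labels, feats = segmented_field
        model = calibrate_classifier(labeled_features)
        out = classify_nuclei(feats, model)
        pred_dead = (out["predicted_class"] == "dead").mean()
        true_dead = np.mean([t.cls == "dead" for t in truth])
        assert abs(pred_dead - true_dead) < 0.03
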