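import numpy as np
import pandas as pd
import pytest

from conftest import small_spec, truth_nuclei
from pccount.errors import (DegenerateTrainingError, ParameterError,
                            UndefinedMetricError)
from pccount.image_io import Image8
from pccount.mereotopology import classify_detections
from pccount.noise import (FEATURE_NAMES, LDAModel, apply_noise_filter,
                           build_training_set, classification_metrics,
                           extract_region_features, features_for_regions,
                           train_lda)
from pccount.segmentation import SegmentationParams, segment_cells
from pccount.synthetic import generate_scene
from test_mereotopology import synthetic_report


def square_region(top, left, size):
    return np.array([(top + i, left + j)
                     for i in range(size) for j in range(size)])


class TestFeatures:
    def test_solid_square_on_constant_image(self):
        img = Image8(np.full((20, 20), 100, np.uint8))
        f = extract_region_features(square_region(5, 5, 3), img)
        assert f["area"] == 9
        assert f["grey_mean"] == 100
        assert f["grey_sd"] == 0
        assert f["grey_skewness"] == 0

    def test_single_pixel_region(self):
        img = Image8(np.full((5, 5), 42, np.uint8))
        f = extract_region_features(np.array([[2, 2]]), img)
        assert f["area"] == 1
        assert f["solidity"] == 1
        assert f["aspect_ratio"] == 1

    def test_rectangle_feret_matches_rotation_oracle(self):
        img = Image8(np.zeros((40, 40), np.uint8))
        coords = np.array([(10 + i, 5 + j)
                           for i in range(5) for j in range(20)])
        f = extract_region_features(coords, img)
        # oracle: caliper width of the pixel-centre hull over 360 angles,
        # plus one pixel for the unit-square footprint
        pts = coords.astype(float)
        widths = []
        for theta in np.linspace(0, np.pi, 360, endpoint=False):
            d = pts @ np.array([np.cos(theta), np.sin(theta)])
            widths.append(d.max() - d.min())
        widths = np.array(widths) + 1.0
        assert f["feret_max"] == pytest.approx(widths.max(), rel=0.01)
        assert f["feret_min"] == pytest.approx(widths.min(), rel=0.01)
        assert f["aspect_ratio"] == pytest.approx(widths.max() / widths.min(),
                                                  rel=0.02)

    def test_circularity_bounded(self):
        img = Image8(np.zeros((30, 30), np.uint8))
        yy, xx = np.mgrid[:30, :30]
        coords = np.argwhere(np.hypot(yy - 15, xx - 15) <= 8)
        f = extract_region_features(coords, img)
        assert 0 < f["circularity"] <= 1
        assert f["circularity"] > 0.8  # a disc is nearly circular

    def test_out_of_bounds_rejected(self):
        img = Image8(np.zeros((5, 5), np.uint8))
        with pytest.raises(ParameterError):
            extract_region_features(np.array([[4, 5]]), img)


class TestTrainingSet:
    def test_merged_and_split_relabelled_as_cells(self):
        report = synthetic_report(correct=3, merged_regions=1,
                                  merged_nuclei=2, split_regions=2,
                                  split_nuclei=1, noise=2)
        n = report.n_regions
        table = pd.DataFrame(np.zeros((n, len(FEATURE_NAMES))),
                             columns=FEATURE_NAMES,
                             index=range(1, n + 1))
        out = build_training_set([report], [table])
        assert (out["label"] == "cell").sum() == 6   # 3 + 1 + 2
        assert (out["label"] == "noise").sum() == 2

    def test_ppi_regions_excluded(self):
        report = synthetic_report(correct=2, noise=1)
        report.region_labels[4] = "ppi"
        report.nucleus_labels[3] = "in_ppi"
        table = pd.DataFrame(np.zeros((4, len(FEATURE_NAMES))),
                             columns=FEATURE_NAMES, index=range(1, 5))
        out = build_training_set([report], [table])
        assert len(out) == 3

    def test_single_class_rejected(self):
        report = synthetic_report(correct=4)
        table = pd.DataFrame(np.zeros((4, len(FEATURE_NAMES))),
                             columns=FEATURE_NAMES, index=range(1, 5))
        with pytest.raises(DegenerateTrainingError):
            build_training_set([report], [table])


def gaussian_table(rng, n=200, separation=10.0, n_features=4):
    a = rng.normal(0.0, 1.0, (n, n_features))
    b = rng.normal(0.0, 1.0, (n, n_features))
    b[:, 0] += separation
    frame = pd.DataFrame(np.vstack([a, b]),
                         columns=[f"f{i}" for i in range(n_features)])
    frame["label"] = ["noise"] * n + ["cell"] * n
    return frame


class TestTrainLDA:
    def test_separable_classes_learned(self, rng):
        model = train_lda(gaussian_table(rng, separation=10.0))
        assert model.training_accuracy >= 0.99

    def test_identical_classes_at_chance(self, rng):
        model = train_lda(gaussian_table(rng, n=1000, separation=0.0,
                                         n_features=2))
        assert model.training_accuracy == pytest.approx(0.5, abs=0.05)

    def test_one_dimensional_threshold_between_classes(self, rng):
        x = np.concatenate([rng.normal(-1, 0.1, 100), rng.normal(1, 0.1, 100)])
        frame = pd.DataFrame({"f0": x,
                              "label": ["noise"] * 100 + ["cell"] * 100})
        model = train_lda(frame)
        # decision boundary in raw units: where the discriminant is zero
        boundary = -model.intercept / model.weights[0] * model.scales[0] \
            + model.means[0]
        assert -0.5 < boundary < 0.5

    def test_too_few_samples_rejected(self):
        frame = pd.DataFrame({"f0": [0.0, 1.0], "label": ["cell", "noise"]})
        with pytest.raises(DegenerateTrainingError):
            train_lda(frame)

    def test_json_roundtrip_preserves_decisions(self, rng, tmp_path):
        table = gaussian_table(rng, separation=3.0)
        model = train_lda(table)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LDAModel.from_json(path)
        np.testing.assert_allclose(back.decision(table),
                                   model.decision(table))


@pytest.fixture(scope="module")
def trained_on_scenes():
    params = SegmentationParams(7, 13)
    reports, tables = [], []
    for k in range(3):
        spec = small_spec(shape=(400, 400), n_cells=25, n_noise_blobs=12,
                          seed=700 + k)
        pc, _, truth = generate_scene(spec)
        regions = segment_cells(pc, params)
        reports.append(classify_detections(regions, truth_nuclei(truth)))
        tables.append(features_for_regions(regions, pc))
    return train_lda(build_training_set(reports, tables)), params


class TestApplyNoiseFilter:
    def test_empty_regions_pass_through(self, trained_on_scenes):
        from pccount.segmentation import LabeledRegions

        model, _ = trained_on_scenes
        img = Image8(np.full((30, 30), 100, np.uint8))
        empty = LabeledRegions(np.zeros((30, 30), np.int64), source=img)
        assert apply_noise_filter(empty, img, model).n_regions == 0

    def test_idempotent(self, trained_on_scenes):
        model, params = trained_on_scenes
        spec = small_spec(shape=(400, 400), n_cells=25, n_noise_blobs=12,
                          seed=911)
        pc, _, _ = generate_scene(spec)
        once = apply_noise_filter(segment_cells(pc, params), pc, model)
        twice = apply_noise_filter(once, pc, model)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_removes_planted_artifacts_keeps_cells(self, trained_on_scenes):
        """Averaged over 10 held-out scenes of 30 cells + 10 planted
        debris blobs: most artifact detections are removed and nearly all
        cells survive."""
        model, params = trained_on_scenes
        kept_cells = cells = hits_before = hits_after = 0
        for seed in range(10):
            spec = small_spec(shape=(400, 400), n_cells=30, n_noise_blobs=10,
                              seed=5000 + seed)
            pc, _, truth = generate_scene(spec)
            before = segment_cells(pc, params)
            after = apply_noise_filter(before, pc, model)
            rep_before = classify_detections(before, truth_nuclei(truth))
            rep_after = classify_detections(after, truth_nuclei(truth))
            cells += rep_before.region_counts()["correct_cell"]
            kept_cells += rep_after.region_counts()["correct_cell"]
            # artifact detections = segmented regions overlapping a blob
            blob = truth.noise_labels > 0
            hits_before += int(np.count_nonzero(
                np.unique(before.labels[blob])))
            hits_after += int(np.count_nonzero(np.unique(after.labels[blob])))
        removed = hits_before - hits_after
        assert removed / max(hits_before, 1) >= 0.7
        assert kept_cells / cells >= 28 / 30


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        m = classification_metrics(["cell", "noise"], ["cell", "noise"])
        assert m.precision == m.recall == m.f1 == 1.0

    def test_f1_equals_p_when_p_equals_r(self):
        # 3 TP, 1 FP, 1 FN -> p = r = 0.75 -> F1 = 0.75
        pred = ["cell"] * 4 + ["noise"] * 1
        truth = ["cell"] * 3 + ["noise"] + ["cell"]
        m = classification_metrics(pred, truth)
        assert m.precision == m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_reported_confusion_matrix_reproduces_f1(self):
        from pccount.noise import ClassifierMetrics

        # counts implied by retaining 96.3% of 1286 cells and removing
        # 78.9% of 280 noise regions
        m = ClassifierMetrics(tp=1238, tn=221, fp=59, fn=48)
        assert m.f1 == pytest.approx(0.959, abs=0.002)

    def test_f1_ignores_true_negatives(self):
        from pccount.noise import ClassifierMetrics

        a = ClassifierMetrics(tp=10, tn=0, fp=3, fn=2)
        b = ClassifierMetrics(tp=10, tn=99999, fp=3, fn=2)
        assert a.f1 == b.f1

    def test_undefined_metrics_raise(self):
        m = classification_metrics(["noise", "noise"], ["cell", "noise"])
        with pytest.raises(UndefinedMetricError):
            m.precision
        m2 = classification_metrics(["noise"], ["noise"])
        with pytest.raises(UndefinedMetricError):
            m2.recall

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            classification_metrics(["cell"], ["cell", "noise"])
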