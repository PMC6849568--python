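"""Noise-region rejection with a linear discriminant on region features.

Segmented regions that overlap no nucleus in the ground truth are spurious
("noise") and inflate the cell count; regions whose only defect is merging
or splitting look morphologically like cells and largely cancel in the
count, so they are relabelled as cells for training.  A two-class Fisher
discriminant is trained on per-region morphology (area, perimeter,
circularity, Feret diameters, aspect ratio, solidity) and greyscale
statistics measured on the original phase-contrast image (mean, sd, min,
max, median, skewness, kurtosis), then applied to delete predicted-noise
regions from future segmentations.

Regions in a one-to-one PPi relation with a nucleus are excluded from
training and are never candidates for removal: they still satisfy the
exclusive one-to-one condition, so deleting them would harm the count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kurtosis, skew
from skimage import measure

from .errors import (DegenerateTrainingError, ParameterError,
                     UndefinedMetricError)
from .image_io import Image8
from .mereotopology import DetectionReport
from .segmentation import LabeledRegions

FEATURE_NAMES = [
    "area", "perimeter", "circularity", "feret_max", "feret_min",
    "aspect_ratio", "solidity", "grey_mean", "grey_sd", "grey_min",
    "grey_max", "grey_median", "grey_skewness", "grey_kurtosis",
]


def _feret_diameters(coords: np.ndarray) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters of a pixel set.

    Pixels are treated as unit squares (corners at +-0.5), so a single
    pixel has Feret diameters (sqrt(2), 1) before the 1-px floor; we
    report the caliper over pixel centres plus one pixel of width, which
    gives 1.0 for a single pixel and n for an n-pixel straight line.
    """
    pts = coords.astype(np.float64)
    if len(pts) == 1:
        return 1.0, 1.0
    try:
        hull = ConvexHull(pts)
        vertices = pts[hull.vertices]
    except QhullError:  # collinear pixels
        vertices = pts
    # max: largest pairwise distance between hull vertices
    diffs = vertices[:, None, :] - vertices[None, :, :]
    dists = np.hypot(diffs[..., 0], diffs[..., 1])
    feret_max = float(dists.max()) + 1.0
    # min: smallest width over directions perpendicular to hull edges
    edges = np.roll(vertices, -1, axis=0) - vertices
    norms = np.hypot(edges[:, 0], edges[:, 1])
    keep = norms > 0
    if not keep.any():
        return feret_max, 1.0
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], axis=1) / norms[keep, None]
    proj = vertices @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    feret_min = float(widths.min()) + 1.0
    return feret_max, feret_min


def extract_region_features(coords: np.ndarray, source: Image8) -> dict[str, float]:
    """Feature vector of one region given its (row, col) pixel coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=int))
    if coords.size == 0:
        raise ParameterError("region must be non-empty")
    h, w = source.shape
    if (coords[:, 0].min() < 0 or coords[:, 0].max() >= h
            or coords[:, 1].min() < 0 or coords[:, 1].max() >= w):
        raise ParameterError("region extends outside the image")
    # rasterise the region into a tight crop for the shape measurements
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    crop = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=np.uint8)
    crop[coords[:, 0] - r0, coords[:, 1] - c0] = 1
    props = measure.regionprops(crop)[0]
    area = float(props.area)
    perimeter = float(props.perimeter) if props.perimeter > 0 else 1.0
    circularity = min(4.0 * np.pi * area / perimeter**2, 1.0)
    feret_max, feret_min = _feret_diameters(coords)
    values = source.pixels[coords[:, 0], coords[:, 1]].astype(np.float64)
    sd = float(values.std())
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": circularity,
        "feret_max": feret_max,
        "feret_min": feret_min,
        "aspect_ratio": feret_max / feret_min,
        "solidity": float(props.solidity),
        "grey_mean": float(values.mean()),
        "grey_sd": sd,
        "grey_min": float(values.min()),
        "grey_max": float(values.max()),
        "grey_median": float(np.median(values)),
        "grey_skewness": float(skew(values)) if sd > 0 else 0.0,
        "grey_kurtosis": float(kurtosis(values)) if sd > 0 else 0.0,
    }


def features_for_regions(regions: LabeledRegions,
                         source: Image8 | None = None) -> pd.DataFrame:
    """Feature table for every region, indexed by region label."""
    src = source if source is not None else regions.source
    if src is None:
        raise ParameterError("a source image is required for grey features")
    rows = {}
    for label in regions.region_ids:
        rows[label] = extract_region_features(regions.region_coords(label), src)
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=FEATURE_NAMES, dtype=float)
    frame.index.name = "region"
    return frame


def build_training_set(reports: list[DetectionReport],
                       feature_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Two-class labelled table: cell (correct + merged + split) vs noise.

    PPi regions are dropped.  Raises if either class ends up empty.
    """
    if len(reports) != len(feature_tables):
        raise ParameterError("reports and feature tables must be paired")
    frames = []
    for report, table in zip(reports, feature_tables):
        labels = {}
        for region, category in report.region_labels.items():
            if category == "ppi":
                continue
            if region not in table.index:
                raise ParameterError(f"no features for region {region}")
            labels[region] = "noise" if category == "noise" else "cell"
        sub = table.loc[list(labels)].copy()
        sub["label"] = [labels[r] for r in sub.index]
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    counts = out["label"].value_counts()
    if counts.get("cell", 0) == 0 or counts.get("noise", 0) == 0:
        raise DegenerateTrainingError(
            "both a cell and a noise class are required for training")
    return out


@dataclass
class LDAModel:
    """Serialisable two-class linear discriminant (cell vs noise).

    Features are standardised (mean/scale stored) and the discriminant is
    the Fisher direction with the threshold at equal class posteriors
    under empirical priors.  ``decision > 0`` means "cell".
    """

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    weights: np.ndarray
    intercept: float
    priors: dict[str, float]
    training_accuracy: float | None = None

    def decision(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=float)
        z = (x - self.means) / self.scales
        return z @ self.weights + self.intercept

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.where(self.decision(table) > 0, "cell", "noise")

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "priors": self.priors,
            "training_accuracy": self.training_accuracy,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LDAModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(feature_names=payload["feature_names"],
                   means=np.asarray(payload["means"]),
                   scales=np.asarray(payload["scales"]),
                   weights=np.asarray(payload["weights"]),
                   intercept=float(payload["intercept"]),
                   priors=payload["priors"],
                   training_accuracy=payload.get("training_accuracy"))


def train_lda(table: pd.DataFrame,
              feature_names: list[str] | None = None) -> LDAModel:
    """Fit the two-class discriminant on a labelled feature table.

    The table must contain the feature columns plus a ``label`` column
    with values "cell" / "noise" and at least two samples of each.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    feature_names = feature_names or [c for c in table.columns if c != "label"]
    labels = table["label"].to_numpy()
    for cls_name in ("cell", "noise"):
        if (labels == cls_name).sum() < 2:
            raise DegenerateTrainingError(
                f"need >= 2 samples of class {cls_name!r}")
    x = table[feature_names].to_numpy(dtype=float)
    means = x.mean(axis=0)
    scales = x.std(axis=0)
    scales[scales == 0] = 1.0
    z = (x - means) / scales
    y = (labels == "cell").astype(int)
    lda = LinearDiscriminantAnalysis()  # svd solver: robust to collinearity
    lda.fit(z, y)
    weights = lda.coef_[0]
    intercept = float(lda.intercept_[0])
    if not np.all(np.isfinite(weights)):
        raise ArithmeticError("discriminant weights are not finite")
    model = LDAModel(feature_names=feature_names, means=means, scales=scales,
                     weights=weights, intercept=intercept,
                     priors={"noise": float(np.mean(y == 0)),
                             "cell": float(np.mean(y == 1))})
    predicted = model.predict(table)
    model.training_accuracy = float(np.mean(predicted == labels))
    return model


def apply_noise_filter(regions: LabeledRegions, source: Image8,
                       model: LDAModel) -> LabeledRegions:
    """Delete predicted-noise regions and relabel the rest contiguously."""
    if model.weights is None or not len(model.weights):
        raise ParameterError("model is not trained")
    if regions.n_regions == 0:
        return LabeledRegions(regions.labels.copy(), source=source,
                              kind=regions.kind)
    table = features_for_regions(regions, source)
    predicted = model.predict(table)
    keep = [label for label, p in zip(table.index, predicted) if p == "cell"]
    mapping = np.zeros(regions.labels.max() + 1, dtype=np.int64)
    for new, old in enumerate(keep, start=1):
        mapping[old] = new
    return LabeledRegions(mapping[regions.labels], source=source,
                          kind=regions.kind)


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts and the derived precision / recall / F1 / accuracy."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            raise UndefinedMetricError("precision undefined: TP + FP = 0")
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("recall undefined: TP + FN = 0")
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if p + r == 0:
            raise UndefinedMetricError("F1 undefined: precision = recall = 0")
        return 2.0 * p * r / (p + r)

    @property
    def overall_accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        if total == 0:
            raise UndefinedMetricError("no samples")
        return (self.tp + self.tn) / total


def classification_metrics(predicted, truth,
                           positive_class: str = "cell") -> ClassifierMetrics:
    """Confusion matrix and metrics with ``positive_class`` as positive."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ParameterError("label vectors must have equal length")
    pos_p = predicted == positive_class
    pos_t = truth == positive_class
    return ClassifierMetrics(
        tp=int(np.sum(pos_p & pos_t)),
        tn=int(np.sum(~pos_p & ~pos_t)),
        fp=int(np.sum(pos_p & ~pos_t)),
        fn=int(np.sum(~pos_p & pos_t)),
    )
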