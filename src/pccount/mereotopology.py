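"""RCC5 region relations and the detection taxonomy.

Discrete mereotopology describes the possible parthood relations between
two binary regions in pixel space.  The five-relation calculus RCC5
distinguishes: DR (disconnected), PO (partial overlap), PP (proper part),
PPi (proper part, inverted) and EQ (equal).  Here it scores a cell
segmentation against ground-truth nuclei: a cell is correctly detected when
its nucleus stands in an exclusive one-to-one PP, PO or EQ relation with
exactly one segmented region.  Violations define the misdetection taxonomy:

* a region overlapping no nucleus is ``noise``;
* a region overlapping two or more nuclei is ``merged``;
* a nucleus overlapping no region is ``missed``;
* a nucleus overlapping two or more regions marks those regions ``split``;
* a one-to-one pair whose relation is PPi (region strictly inside the
  nucleus) is kept but flagged ``ppi`` — still a one-to-one detection, so
  not a counting error, but not the geometry a correct detection expects.

Entangled cases are resolved by a fixed precedence (region-level labels
first, then nucleus-level, then one-to-one pairs) so that every object gets
exactly one label and the category counts are exact partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .segmentation import LabeledRegions


class RCC5(Enum):
    """The five RCC5 relations between ordered regions (X, Y)."""

    DR = "DR"    # disconnected
    PO = "PO"    # partial overlap
    PP = "PP"    # X is a proper part of Y
    PPI = "PPi"  # Y is a proper part of X
    EQ = "EQ"    # equal


def rcc5_relation(x, y) -> RCC5:
    """RCC5 relation between two non-empty pixel sets.

    Accepts any iterables of (row, col) pixels (sets, lists or (N, 2)
    arrays).
    """
    xs = x if isinstance(x, set) else {tuple(p) for p in x}
    ys = y if isinstance(y, set) else {tuple(p) for p in y}
    if not xs or not ys:
        raise ParameterError("regions must be non-empty")
    return _relation_from_sizes(len(xs & ys), len(xs), len(ys))


def _relation_from_sizes(overlap: int, nx: int, ny: int) -> RCC5:
    if overlap == 0:
        return RCC5.DR
    if overlap == nx == ny:
        return RCC5.EQ
    if overlap == nx:
        return RCC5.PP
    if overlap == ny:
        return RCC5.PPI
    return RCC5.PO


#: Region labels (segmented cell candidates).
REGION_CATEGORIES = ("correct_cell", "merged", "split", "noise", "ppi")
#: Nucleus labels (ground truth).
NUCLEUS_CATEGORIES = ("detected", "missed", "in_merged", "in_split", "in_ppi")


@dataclass
class DetectionReport:
    """Per-object detection labels and their summary rates."""

    region_labels: dict[int, str]
    nucleus_labels: dict[int, str]
    pair_relations: dict[tuple[int, int], RCC5] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.region_labels.values():
            if v not in REGION_CATEGORIES:
                raise ParameterError(f"unknown region label {v!r}")
        for v in self.nucleus_labels.values():
            if v not in NUCLEUS_CATEGORIES:
                raise ParameterError(f"unknown nucleus label {v!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_labels)

    def region_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(REGION_CATEGORIES, 0)
        for v in self.region_labels.values():
            counts[v] += 1
        return counts

    def nucleus_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(NUCLEUS_CATEGORIES, 0)
        for v in self.nucleus_labels.values():
            counts[v] += 1
        return counts

    @property
    def correct_detection_rate(self) -> float:
        if self.n_nuclei == 0:
            raise UndefinedMetricError("no nuclei in the ground truth")
        return self.region_counts()["correct_cell"] / self.n_nuclei

    def summary(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "n_nuclei": self.n_nuclei,
            "regions": self.region_counts(),
            "nuclei": self.nucleus_counts(),
            "correct_detection_rate": self.correct_detection_rate
            if self.n_nuclei else None,
        }


def _overlap_table(cells: np.ndarray, nuclei: np.ndarray):
    """Pairwise pixel-overlap counts between two label rasters."""
    n_c = int(cells.max())
    n_n = int(nuclei.max())
    both = (cells > 0) & (nuclei > 0)
    pair_ids = cells[both].astype(np.int64) * (n_n + 1) + nuclei[both]
    counts = np.bincount(pair_ids, minlength=(n_c + 1) * (n_n + 1))
    overlap = counts.reshape(n_c + 1, n_n + 1)[1:, 1:]  # [region-1, nucleus-1]
    return overlap


def classify_detections(cells: LabeledRegions,
                        nuclei: LabeledRegions) -> DetectionReport:
    """Label every segmented region and every nucleus per the taxonomy.

    "Overlap" means at least one shared pixel.  Precedence for entangled
    configurations: region-level labels (noise, merged) are fixed first,
    then nucleus-level labels (missed, split), and the remaining strict
    one-to-one pairs are scored by their RCC5 relation (PP/PO/EQ ->
    correct; PPi -> flagged).
    """
    if cells.labels.shape != nuclei.labels.shape:
        raise ParameterError("cell and nucleus rasters must share geometry")
    cl, nl = cells.labels, nuclei.labels
    n_c, n_n = int(cl.max()), int(nl.max())
    overlap = _overlap_table(cl, nl)
    c_areas = np.bincount(cl.ravel(), minlength=n_c + 1)[1:]
    n_areas = np.bincount(nl.ravel(), minlength=n_n + 1)[1:]

    region_labels: dict[int, str] = {}
    nucleus_labels: dict[int, str] = {}
    pair_relations: dict[tuple[int, int], RCC5] = {}
    for ci in range(n_c):
        for ni in np.nonzero(overlap[ci])[0]:
            pair_relations[(int(ni) + 1, ci + 1)] = _relation_from_sizes(
                int(overlap[ci, ni]), int(n_areas[ni]), int(c_areas[ci]))

    nuclei_per_region = (overlap > 0).sum(axis=1)
    regions_per_nucleus = (overlap > 0).sum(axis=0)

    def _ids(indices):
        return [int(i) + 1 for i in indices]

    # 1-2. region-level: noise, merged
    for ci in range(n_c):
        if nuclei_per_region[ci] == 0:
            region_labels[ci + 1] = "noise"
        elif nuclei_per_region[ci] >= 2:
            region_labels[ci + 1] = "merged"
    # 3-4. nucleus-level: missed, split
    for ni in range(n_n):
        if regions_per_nucleus[ni] == 0:
            nucleus_labels[ni + 1] = "missed"
        elif regions_per_nucleus[ni] >= 2:
            nucleus_labels[ni + 1] = "in_split"
            for ci in _ids(np.nonzero(overlap[:, ni])[0]):
                region_labels.setdefault(ci, "split")
    # 5. nuclei whose single region was consumed by a merge
    for ni in range(n_n):
        if ni + 1 in nucleus_labels:
            continue
        (ci,) = _ids(np.nonzero(overlap[:, ni])[0])
        if region_labels.get(ci) == "merged":
            nucleus_labels[ni + 1] = "in_merged"
    # 6. remaining strict one-to-one pairs
    for ni in range(n_n):
        if ni + 1 in nucleus_labels:
            continue
        (ci,) = _ids(np.nonzero(overlap[:, ni])[0])
        rel = pair_relations[(ni + 1, ci)]
        if rel is RCC5.PPI:
            region_labels[ci] = "ppi"
            nucleus_labels[ni + 1] = "in_ppi"
        else:  # PP, PO or EQ
            region_labels[ci] = "correct_cell"
            nucleus_labels[ni + 1] = "detected"

    return DetectionReport(region_labels=region_labels,
                           nucleus_labels=nucleus_labels,
                           pair_relations=pair_relations)


def pool_reports(reports: list[DetectionReport]) -> tuple[int, int]:
    """Pooled (correct detections, total nuclei) across several images."""
    correct = sum(r.region_counts()["correct_cell"] for r in reports)
    total = sum(r.n_nuclei for r in reports)
    return correct, total


def error_contributions(report: DetectionReport) -> dict[str, float]:
    """Signed count-error contribution of each misdetection type.

    Each contribution is the change the category induces in the final
    count, as a percentage of the number of correctly detected cells:
    noise adds one region each; a merged region replaces its k nuclei with
    one region (net -(k-1) per region); a split nucleus turns into k
    regions (net +(k-1) per nucleus); a missed nucleus subtracts one.
    """
    rc = report.region_counts()
    nc = report.nucleus_counts()
    correct = rc["correct_cell"]
    if correct == 0:
        raise UndefinedMetricError(
            "error contributions are undefined with zero correct detections")
    scale = 100.0 / correct
    return {
        "noise": scale * rc["noise"],
        "split": scale * (rc["split"] - nc["in_split"]),
        "merged": -scale * (nc["in_merged"] - rc["merged"]),
        "missed": -scale * nc["missed"],
    }
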