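"""Cell segmentation by dual mean-filter subtraction.

Phase-contrast images of epithelial monolayers show dark cell interiors
ringed by a bright halo artefact, which defeats direct intensity
thresholding.  A mean filter whose kernel is large enough to span a cell
averages the bright halo into the interior, so the filtered interior becomes
*brighter* than in the lightly smoothed image.  Subtracting a small-radius
filtered copy from a large-radius filtered copy therefore produces an image
in which cell bodies are the bright class, which a global Otsu threshold can
separate; small residual specks are removed by a minimum-area rule and the
number of connected components is the per-image cell count.

The kernel is a discrete disk {(dx, dy) : dx^2 + dy^2 <= r^2} and image
borders are handled by edge replication, so a constant image maps to itself
for every radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .errors import DegenerateImageError, ParameterError
from .image_io import BinaryMask, Image8, ImageF

#: Connectivity used for connected-component analysis (8-connectivity).
CONNECTIVITY = 2


@dataclass(frozen=True)
class SegmentationParams:
    """Radii of the two mean filters and the minimum region area.

    ``r_small`` smooths fine detail inside cells with minimal change in
    intensity; ``r_large`` must span a cell so that interiors brighten.
    Regions smaller than ``min_area`` pixels are discarded as specks.
    Defaults are the radii selected for H400 oral keratinocytes at a x10
    objective (7 and 22 px, i.e. ~6 and ~20 um) and an 8-px area floor.
    """

    r_small: int = 7
    r_large: int = 22
    min_area: int = 8

    def __post_init__(self) -> None:
        if self.r_small < 1:
            raise ParameterError("r_small must be >= 1")
        if self.r_large <= self.r_small:
            raise ParameterError("r_large must exceed r_small")
        if self.min_area < 1:
            raise ParameterError("min_area must be >= 1")


@dataclass
class LabeledRegions:
    """Connected foreground regions of one image.

    ``labels`` is an integer raster with 0 = background and labels
    1..n_regions for the regions; ``source`` optionally references the
    originating image so that greyscale features can be measured later.
    """

    labels: np.ndarray
    source: Image8 | None = None
    kind: str = "cell"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ParameterError("labels must be a 2-D raster")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def region_coords(self, label: int) -> np.ndarray:
        """(N, 2) array of (row, col) pixel coordinates of one region."""
        return np.argwhere(self.labels == label)

    @property
    def regions(self) -> dict[int, np.ndarray]:
        return {i: self.region_coords(i) for i in self.region_ids}

    def areas(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel())
        return {i: int(counts[i]) for i in self.region_ids}


@dataclass
class IntensityProfile:
    """Mean in-cell intensity after mean filtering, as a function of radius."""

    radii: list[int]
    mean_intensities: list[float]

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.mean_intensities):
            raise ParameterError("one intensity per radius required")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ParameterError("radii must be strictly increasing")

    @property
    def argmax_radius(self) -> int:
        return self.radii[int(np.argmax(self.mean_intensities))]


def disk_offsets(radius: int) -> np.ndarray:
    """Row offsets and half-widths of the disk kernel's horizontal runs."""
    dy = np.arange(-radius, radius + 1)
    half = np.floor(np.sqrt(radius * radius - dy * dy)).astype(int)
    return np.stack([dy, half], axis=1)


def disk_kernel_size(radius: int) -> int:
    """Number of pixels in the disk kernel of the given radius."""
    return int((2 * disk_offsets(radius)[:, 1] + 1).sum()) if radius > 0 else 1


def _mean_filter_array(pixels: np.ndarray, radius: int) -> np.ndarray:
    # Disk kernel decomposed into horizontal runs; each run is a sliding
    # window sum over a row, computed from a padded cumulative sum.  Exact
    # to floating-point rounding and O(N * r) rather than O(N * r^2).
    if radius == 0:
        return pixels.astype(np.float64, copy=True)
    padded = np.pad(pixels.astype(np.float64), radius, mode="edge")
    csum = np.cumsum(padded, axis=1)
    csum = np.pad(csum, ((0, 0), (1, 0)))  # csum[:, j] = sum of cols < j
    h, w = pixels.shape
    acc = np.zeros((h, w), dtype=np.float64)
    npix = 0
    for dy, half in disk_offsets(radius):
        rows = slice(radius + dy, radius + dy + h)
        # window over padded columns [radius - half, radius + half] per pixel
        lo = radius - half
        hi = radius + half + 1
        acc += csum[rows, hi : hi + w] - csum[rows, lo : lo + w]
        npix += 2 * half + 1
    return acc / npix


def mean_filter(image: Image8 | ImageF, radius: int) -> ImageF:
    """Mean filter with a disk kernel of the given radius in pixels.

    Each output pixel is the arithmetic mean of the input pixels within the
    disk {dx^2 + dy^2 <= r^2} centred on it; borders are handled by edge
    replication.  Radius 0 returns the input unchanged.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    return ImageF(_mean_filter_array(np.asarray(image.pixels), radius),
                  pixel_size=image.pixel_size)


def dual_filter_subtract(image: Image8, params: SegmentationParams,
                         *, _r_small: int | None = None) -> ImageF:
    """Difference of the two mean-filtered copies (large minus small).

    Cell interiors — dark in the lightly smoothed copy, brightened in the
    heavily smoothed copy — become positive in the result.
    """
    r_small = params.r_small if _r_small is None else _r_small
    big = _mean_filter_array(image.pixels, params.r_large)
    small = _mean_filter_array(image.pixels, r_small)
    return ImageF(big - small, pixel_size=image.pixel_size)


def otsu_binarize(image: ImageF) -> BinaryMask:
    """Binarise with Otsu's threshold on a 256-bin histogram.

    The signed input is min-max rescaled to [0, 255] first; the threshold
    maximises the between-class variance (ties broken toward the lowest
    threshold) and pixels strictly above it become foreground.
    """
    pixels = image.pixels
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        raise DegenerateImageError("constant image: no threshold exists")
    scaled = (pixels - lo) * (255.0 / (hi - lo))
    hist, _ = np.histogram(scaled, bins=256, range=(0.0, 256.0))
    thresh = _otsu_threshold(hist)
    return BinaryMask((scaled > thresh).astype(np.uint8),
                      pixel_size=image.pixel_size)


def _otsu_threshold(hist: np.ndarray) -> float:
    """Between-class-variance-maximising cut on a 256-bin histogram.

    Returns the upper edge of the last background bin, so foreground is
    "strictly above".  Ties take the lowest threshold.
    """
    hist = hist.astype(np.float64)
    centers = np.arange(256, dtype=np.float64) + 0.5
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m = np.cumsum(hist * centers)
    mu0 = np.divide(m[:-1], w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(m[-1] - m[:-1], w1, out=np.zeros_like(w1), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(np.argmax(between) + 1)  # upper edge of bin argmax


def remove_small_regions(mask: BinaryMask, min_area: int = 8) -> BinaryMask:
    """Delete connected components with area strictly below ``min_area``.

    The comparison is strict: with the default floor of 8 px a 7-px region
    is removed and an 8-px region is kept.
    """
    boolean = mask.pixels.astype(bool)
    # max_size removes components with area <= its value, so min_area - 1
    # implements the strict "area < min_area" rule
    kept = morphology.remove_small_objects(boolean, max_size=min_area - 1,
                                           connectivity=CONNECTIVITY)
    return BinaryMask(kept.astype(np.uint8), pixel_size=mask.pixel_size)


def segment_cells(image: Image8, params: SegmentationParams) -> LabeledRegions:
    """Full segmentation workflow: filter, subtract, threshold, clean, label.

    Raises :class:`DegenerateImageError` on a constant (blank) field of
    view, which callers may report as a count of zero.
    """
    diff = dual_filter_subtract(image, params)
    # 8-bit subtraction semantics: negative differences (the halo ring,
    # which is brighter in the lightly smoothed copy) clip to zero and
    # join the background, leaving a clean bimodal histogram for Otsu
    clipped = ImageF(np.maximum(diff.pixels, 0.0), pixel_size=diff.pixel_size)
    mask = otsu_binarize(clipped)
    mask = remove_small_regions(mask, params.min_area)
    labels = measure.label(mask.pixels, connectivity=CONNECTIVITY)
    return LabeledRegions(labels, source=image)


def probe_intensity_vs_radius(image: Image8, sample_points, radii) -> IntensityProfile:
    """Mean filtered intensity at sample points for a sweep of kernel radii.

    Used to locate the radius at which in-cell intensity peaks (the
    smallest kernel that spans a cell and its halo), which guides the
    choice of the search range for ``r_large``.
    """
    points = np.atleast_2d(np.asarray(sample_points, dtype=int))
    radii = [int(r) for r in radii]
    if not radii:
        raise ParameterError("radii must be non-empty")
    h, w = image.shape
    if (points[:, 0].min() < 0 or points[:, 0].max() >= h
            or points[:, 1].min() < 0 or points[:, 1].max() >= w):
        raise ParameterError("sample point out of image bounds")
    means = []
    for r in radii:
        filtered = _mean_filter_array(image.pixels, r)
        means.append(float(filtered[points[:, 0], points[:, 1]].mean()))
    return IntensityProfile(radii=radii, mean_intensities=means)
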