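"""From per-image counts to whole-culture estimates and growth curves.

A culture is sampled by imaging n fields of view at random locations; the
whole-culture count is the mean per-image count scaled by the ratio of
substrate area to field-of-view area:

    N_total = (A_total / A_image) * mean(N_image)

For a 35 mm dish imaged with a 1.19 x 0.89 mm field this multiplier is
962.11 / 1.06 = 907.65.  How many fields are enough is decided from the
convergence of the running mean: Delta-C(n) is the magnitude of the
relative change in the mean count when the n-th image is added, and the
recommended n is the point past which Delta-C stays below a threshold
(default 1.5%).  A through-origin regression of image-analysis counts on
reference counts validates the method; repeated estimates over time give
growth curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedMetricError

#: Field-of-view area of the reference acquisition setup, mm^2
#: (1.19 mm x 0.89 mm).
DEFAULT_IMAGE_AREA_MM2 = 1.06


def dish_area(diameter_mm: float) -> float:
    """Substrate area of a circular culture dish, mm^2."""
    if diameter_mm <= 0:
        raise ParameterError("diameter must be positive")
    return float(np.pi * (diameter_mm / 2.0) ** 2)


@dataclass(frozen=True)
class CultureEstimate:
    """Whole-culture count extrapolated from per-image means."""

    n_total: float
    a_total_mm2: float
    a_image_mm2: float
    mean_per_image: float
    n_images: int = 0
    sd_per_image: float = float("nan")

    @property
    def multiplier(self) -> float:
        return self.a_total_mm2 / self.a_image_mm2


def estimate_total(mean_per_image: float, a_total_mm2: float,
                   a_image_mm2: float = DEFAULT_IMAGE_AREA_MM2,
                   n_images: int = 0,
                   sd_per_image: float = float("nan")) -> CultureEstimate:
    """Extrapolate a mean per-image count to the whole culture vessel."""
    if a_image_mm2 <= 0 or a_total_mm2 <= 0:
        raise ParameterError("areas must be positive")
    if a_total_mm2 < a_image_mm2:
        raise ParameterError("substrate area must be >= field-of-view area")
    n_total = (a_total_mm2 / a_image_mm2) * mean_per_image
    return CultureEstimate(n_total=n_total, a_total_mm2=a_total_mm2,
                           a_image_mm2=a_image_mm2,
                           mean_per_image=mean_per_image,
                           n_images=n_images, sd_per_image=sd_per_image)


@dataclass
class ConvergenceCurve:
    """Delta-C(n) series and the recommended number of fields of view."""

    n: list[int]
    delta_c: list[float]  # percent
    threshold_percent: float
    recommended_n: int | None

    def as_rows(self):
        return list(zip(self.n, self.delta_c))


def convergence_analysis(counts, threshold_percent: float = 1.5) -> ConvergenceCurve:
    """Relative change of the running mean as fields of view accumulate.

    Delta-C(n) = |mean(first n) - mean(first n-1)| / mean(first n) * 100.
    ``recommended_n`` is the smallest n such that Delta-C(m) <= threshold
    for every observed m >= n, or None if even the last point exceeds it.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size < 2:
        raise ParameterError("at least two counts are required")
    running = np.cumsum(counts) / np.arange(1, counts.size + 1)
    if np.any(running == 0):
        raise UndefinedMetricError("running mean of zero: Delta-C undefined")
    ns = list(range(2, counts.size + 1))
    delta = [abs(running[n - 1] - running[n - 2]) / running[n - 1] * 100.0
             for n in ns]
    recommended = None
    for i in range(len(ns)):
        if all(d <= threshold_percent for d in delta[i:]):
            recommended = ns[i]
            break
    return ConvergenceCurve(n=ns, delta_c=delta,
                            threshold_percent=threshold_percent,
                            recommended_n=recommended)


@dataclass(frozen=True)
class ValidationFit:
    """Through-origin regression of image counts on reference counts."""

    gradient: float
    r_squared: float
    count_reference: tuple
    count_image: tuple


def validation_regression(pairs) -> ValidationFit:
    """Fit count_image = gradient * count_reference by least squares.

    The model has no intercept; R^2 is computed against the through-origin
    model (1 - SS_res / sum(y^2)), so an exact proportional relation gives
    R^2 = 1 regardless of the slope.
    """
    pairs = [(float(a), float(b)) for a, b in pairs]
    if len(pairs) < 2:
        raise ParameterError("at least two pairs are required")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.all(x == 0):
        raise ParameterError("all reference counts are zero")
    gradient = float(np.sum(x * y) / np.sum(x * x))
    ss_res = float(np.sum((y - gradient * x) ** 2))
    ss_tot = float(np.sum(y * y))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ValidationFit(gradient=gradient, r_squared=r_squared,
                         count_reference=tuple(x), count_image=tuple(y))


@dataclass
class GrowthPoint:
    """Whole-culture estimates of all replicates at one time point."""

    time_h: float
    estimates: list[CultureEstimate]

    @property
    def mean(self) -> float:
        return float(np.mean([e.n_total for e in self.estimates]))

    @property
    def sd(self) -> float:
        return float(np.std([e.n_total for e in self.estimates], ddof=1)) \
            if len(self.estimates) > 1 else 0.0


@dataclass
class GrowthCurve:
    """Mean +- sd whole-culture counts over time."""

    points: list[GrowthPoint]

    @property
    def times(self) -> list[float]:
        return [p.time_h for p in self.points]

    @property
    def means(self) -> list[float]:
        return [p.mean for p in self.points]

    @property
    def sds(self) -> list[float]:
        return [p.sd for p in self.points]

    def doubling_time_h(self) -> float:
        """Doubling time from a log2-linear fit of the mean curve."""
        t = np.asarray(self.times)
        m = np.asarray(self.means)
        if np.any(m <= 0):
            raise UndefinedMetricError("non-positive mean count in curve")
        slope = np.polyfit(t, np.log2(m), 1)[0]
        if slope <= 0:
            raise UndefinedMetricError("culture is not growing")
        return float(1.0 / slope)


def growth_curve(series: dict[float, list[list[float]]],
                 a_total_mm2: float,
                 a_image_mm2: float = DEFAULT_IMAGE_AREA_MM2) -> GrowthCurve:
    """Whole-culture growth curve from per-time, per-replicate image counts.

    ``series`` maps time (hours post-seeding) to a list of replicates,
    each a list of per-image counts.  Each replicate is extrapolated via
    :func:`estimate_total`; the curve carries mean and sd across
    replicates at each time.
    """
    times = sorted(series)
    if list(series) != times:
        raise ParameterError("time points must be in increasing order")
    points = []
    for t in times:
        replicates = series[t]
        if not replicates or any(len(r) == 0 for r in replicates):
            raise ParameterError(f"empty replicate at t={t}")
        estimates = []
        for counts in replicates:
            counts = np.asarray(counts, dtype=float)
            estimates.append(estimate_total(
                float(counts.mean()), a_total_mm2, a_image_mm2,
                n_images=counts.size,
                sd_per_image=float(counts.std(ddof=1)) if counts.size > 1
                else 0.0))
        points.append(GrowthPoint(time_h=float(t), estimates=estimates))
    return GrowthCurve(points=points)
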