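"""Shared fixtures: synthetic scenes at the scales the tests exercise."""

from __future__ import annotations

import numpy as np
import pytest

from pccount.segmentation import LabeledRegions
from pccount.synthetic import SceneSpec, generate_scene


def clean_spec(**overrides) -> SceneSpec:
    """An idealised scene: full halos, uniform contrast, no texture/noise.

    Used where a test asserts exact recovery; the default (realistic)
    spec is used everywhere robustness is the question.
    """
    base = dict(shape=(420, 420), n_cells=30, n_noise_blobs=0,
                background_noise_sd=0.0, cell_texture_sd=0.0,
                halo_coverage_range=(1.0, 1.0),
                cell_contrast_range=(1.0, 1.0), seed=0)
    base.update(overrides)
    return SceneSpec(**base)


def small_spec(**overrides) -> SceneSpec:
    """A realistic scene small enough for per-test segmentation."""
    base = dict(shape=(300, 300), n_cells=20, cell_radius_mean=10.0,
                cell_radius_sd=1.0, halo_width=3.0, n_noise_blobs=5, seed=0)
    base.update(overrides)
    return SceneSpec(**base)


def truth_nuclei(truth) -> LabeledRegions:
    """Ground-truth nucleus labels wrapped for classification."""
    return LabeledRegions(truth.nucleus_labels, kind="nucleus")


def truth_cells(spec: SceneSpec, truth) -> LabeledRegions:
    """Perfect cell-body label raster reconstructed from ground truth."""
    labels = np.zeros(spec.shape, dtype=np.int64)
    yy, xx = np.mgrid[: spec.shape[0], : spec.shape[1]]
    for i, (center, r) in enumerate(zip(truth.centers, truth.radii), 1):
        labels[np.hypot(yy - center[0], xx - center[1]) <= r] = i
    return LabeledRegions(labels)


@pytest.fixture(scope="session")
def default_scene():
    """One realistic scene at generator defaults (800x600, 50 cells)."""
    spec = SceneSpec(seed=11)
    pc, fluor, truth = generate_scene(spec)
    return spec, pc, fluor, truth


@pytest.fixture(scope="session")
def small_scene():
    spec = small_spec(seed=5)
    pc, fluor, truth = generate_scene(spec)
    return spec, pc, fluor, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_mean_filter(pixels: np.ndarray, radius: int) -> np.ndarray:
    """O(N * k^2) reference mean filter: disk kernel, edge replication."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if radius == 0:
        return pixels.copy()
    padded = np.pad(pixels, radius, mode="edge")
    offsets = [(dy, dx)
               for dy in range(-radius, radius + 1)
               for dx in range(-radius, radius + 1)
               if dy * dy + dx * dx <= radius * radius]
    out = np.zeros_like(pixels)
    h, w = pixels.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = np.mean([padded[i + radius + dy, j + radius + dx]
                                 for dy, dx in offsets])
    return out
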