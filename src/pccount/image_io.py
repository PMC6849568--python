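"""Calibrated greyscale image containers and TIFF/PNG input-output.

All downstream stages consume the three raster types defined here:

``Image8``
    an 8-bit greyscale micrograph with an isotropic spatial calibration
    (micrometres per pixel).  This is the acquisition format: phase-contrast
    and epifluorescence channels are both stored this way.
``ImageF``
    a real-valued intermediate with the same geometry, used for the signed
    output of filtering and subtraction before thresholding.
``BinaryMask``
    a 0/1 raster, e.g. the thresholded segmentation.

Calibration is metadata only: it is attached at read time, propagated
unchanged through every operation, and never alters pixel arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Default calibration in micrometres per pixel: a 1600-pixel-wide field of
#: view spanning 1.19 mm gives 1190 / 1600 = 0.74375 um/px.
DEFAULT_PIXEL_SIZE = 1190.0 / 1600.0


def _check_raster(pixels: np.ndarray) -> None:
    if pixels.ndim != 2:
        raise FormatError(f"expected a 2-D raster, got shape {pixels.shape}")
    if pixels.size == 0:
        raise FormatError("zero-sized raster")


@dataclass
class Image8:
    """8-bit greyscale image with spatial calibration.

    Parameters
    ----------
    pixels
        2-D array; values must lie in [0, 255].  Stored as ``uint8``.
    pixel_size
        Isotropic calibration in micrometres per pixel (> 0).
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        _check_raster(pixels)
        if pixels.dtype != np.uint8:
            if pixels.min() < 0 or pixels.max() > 255:
                raise ParameterError("Image8 values must lie in [0, 255]")
            pixels = pixels.astype(np.uint8)
        self.pixels = pixels
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageF:
    """Real-valued intermediate image sharing geometry with its source."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.float64)
        _check_raster(pixels)
        if not np.all(np.isfinite(pixels)):
            raise ParameterError("ImageF values must be finite")
        self.pixels = pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """0/1 raster with the geometry and calibration of its source image."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        _check_raster(pixels)
        self.pixels = (pixels > 0).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _load_raster(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        return tifffile.imread(path)
    return iio.imread(path)


def read_image(path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> Image8:
    """Read a greyscale image file as a calibrated :class:`Image8`.

    Multi-channel rasters are reduced to a single channel by averaging the
    channels (luminance mean) and >8-bit data are rescaled to [0, 255] by
    max-normalisation; both conversions are logged as warnings because the
    counting pipeline is defined on 8-bit single-channel input.
    """
    pixels = np.asarray(_load_raster(path))
    if pixels.ndim == 3:
        logger.warning("%s: multi-channel input, converting by channel mean", path)
        pixels = pixels.astype(np.float64).mean(axis=-1)
    _check_raster(pixels)
    if pixels.dtype != np.uint8:
        top = float(pixels.max())
        if top > 255:
            logger.warning("%s: >8-bit input, rescaling to [0, 255] by max", path)
            pixels = pixels.astype(np.float64) * (255.0 / top)
        pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    return Image8(pixels, pixel_size=pixel_size)


def write_image(image: Image8, path) -> None:
    """Write an :class:`Image8` to TIFF or PNG; round-trips bit-exactly."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit image with values {0, 255}.

    Any positive value in the input is treated as foreground, so labelled
    images may be passed directly.  ``read_mask`` restores the 0/1 array
    bit-exactly.
    """
    out = (mask.pixels > 0).astype(np.uint8) * 255
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_mask(path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> BinaryMask:
    """Read a mask file; any positive pixel is foreground."""
    pixels = np.asarray(_load_raster(path))
    if pixels.ndim == 3:
        pixels = pixels.max(axis=-1)
    _check_raster(pixels)
    return BinaryMask(pixels, pixel_size=pixel_size)


def write_labels(labels: np.ndarray, path) -> None:
    """Write an integer label image (16-bit TIFF)."""
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.uint16))


def read_labels(path) -> np.ndarray:
    """Read an integer label image written by :func:`write_labels`."""
    return tifffile.imread(str(path)).astype(np.int64)
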