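"""Image carriers and preprocessing: grayscale conversion, linear contrast
stretching and weighted-average (binomial) smoothing.

All rasters are addressed as ``(row, col)`` with ``(0, 0)`` at the top-left.
Internal arithmetic is floating point; intensities are quantised back to
integers only where an operation's contract requires it (grayscale
conversion, contrast stretch) or at file-output boundaries.  Rounding is
nearest integer with ties to even (``numpy.rint``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage


class InvalidImageError(ValueError):
    """The input raster is missing, malformed or too small to process."""


class InvalidConfigurationError(ValueError):
    """A parameter combination that the pipeline cannot honour."""


@dataclass
class RgbImage:
    """An H×W×3 colour raster with a declared bit depth.

    Channel values must lie in ``[0, 2**bit_depth - 1]`` and the raster must
    be at least 3×3 so that a 3×3 filter mask can traverse it.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidImageError(
                f"expected an H×W×3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise InvalidImageError("image must be at least 3×3")
        top = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > top:
            raise InvalidImageError(
                f"channel values outside [0, {top}] for bit depth {self.bit_depth}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class GrayImage:
    """An H×W scalar-intensity raster with a declared bit depth.

    ``graymin`` / ``graymax`` are the observed extrema, recomputed on
    construction so they stay consistent after every transform.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    graymin: float = field(init=False)
    graymax: float = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InvalidImageError(f"expected an H×W raster, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise InvalidImageError("image must be at least 3×3")
        self.pixels = px
        self.graymin = float(px.min())
        self.graymax = float(px.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FilterMask:
    """A normalised (2k+1)×(2k+1) weighted-average mask.

    Coefficients are non-negative, sum to one, and the centre coefficient is
    the largest — the defining property of a weighted-average low-pass
    filter.
    """

    coefficients: np.ndarray
    normalizer: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=np.float64)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] % 2 == 0:
            raise InvalidConfigurationError("mask must be square with odd side")
        if (c < 0).any():
            raise InvalidConfigurationError("mask coefficients must be non-negative")
        if abs(c.sum() - 1.0) > 1e-9:
            raise InvalidConfigurationError("mask coefficients must sum to 1")
        k = c.shape[0] // 2
        if c[k, k] < c.max() - 1e-12:
            raise InvalidConfigurationError("centre coefficient must be the maximum")
        self.coefficients = c

    @property
    def size(self) -> int:
        return self.coefficients.shape[0]

    @classmethod
    def binomial(cls, size: int = 5) -> "FilterMask":
        """Binomial weighted-average mask of odd side ``size``.

        ``size=3`` gives the classic [1 2 1; 2 4 2; 1 2 1]/16 mask;
        ``size=5`` its natural extension, outer([1 4 6 4 1])/256.
        """
        if size < 1 or size % 2 == 0:
            raise InvalidConfigurationError("mask size must be a positive odd integer")
        row = np.array([1.0])
        for _ in range(size - 1):
            row = np.convolve(row, [1.0, 1.0])
        raw = np.outer(row, row)
        return cls(coefficients=raw / raw.sum(), normalizer=float(raw.sum()))


def load_image(path: str | Path, bit_depth: int = 8) -> RgbImage:
    """Read a JPEG/PNG/TIFF file into an :class:`RgbImage`.

    Single-channel files are replicated across the three channels; an alpha
    channel, if present, is dropped.
    """
    try:
        arr = iio.imread(Path(path))
    except (OSError, ValueError) as exc:
        raise InvalidImageError(f"cannot read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(f"unsupported channel layout {arr.shape}")
    return RgbImage(pixels=arr, bit_depth=bit_depth)


def save_png(path: str | Path, pixels: np.ndarray) -> None:
    """Write an intensity or RGB raster to PNG, clipping to 8-bit."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0, 255)
    iio.imwrite(Path(path), np.rint(arr).astype(np.uint8))


def to_grayscale(img: RgbImage) -> GrayImage:
    """Convert RGB to grayscale by the per-pixel channel mean.

    Each output intensity is ``(R + G + B) / 3`` rounded to the nearest
    integer (ties to even); the bit depth is preserved.  Applying the
    conversion to an image with ``R = G = B`` is the identity.
    """
    gray = np.rint(img.pixels.mean(axis=2))
    return GrayImage(pixels=gray, bit_depth=img.bit_depth)


def contrast_enhance(img: GrayImage) -> GrayImage:
    """Linear contrast stretch to the full dynamic range of the bit depth.

    The observed minimum is shifted to zero and intensities are scaled by the
    enhancement factor ``(2**n - 1) / (graymax - graymin)``, so the output
    spans ``[0, 2**n - 1]`` exactly.  A constant image cannot be stretched
    and is returned unchanged with a warning.
    """
    if img.graymax == img.graymin:
        warnings.warn(
            "constant image: contrast enhancement is undefined, returning input unchanged",
            stacklevel=2,
        )
        return GrayImage(pixels=img.pixels.copy(), bit_depth=img.bit_depth)
    factor = (2**img.bit_depth - 1) / (img.graymax - img.graymin)
    out = np.rint((img.pixels - img.graymin) * factor)
    return GrayImage(pixels=out, bit_depth=img.bit_depth)


def weighted_smooth(img: GrayImage, mask: FilterMask) -> GrayImage:
    """Smooth by 2-D correlation with a normalised weighted-average mask.

    Borders are handled by edge replication, which avoids the spurious
    boundary gradients a zero pad would inject into the Hough vote.  Output
    stays within the input intensity range (the mask is a convex
    combination) and is kept in floating point.
    """
    if mask.size > min(img.shape):
        raise InvalidConfigurationError(
            f"{mask.size}×{mask.size} mask does not fit inside image of shape {img.shape}"
        )
    out = ndimage.correlate(img.pixels, mask.coefficients, mode="nearest")
    return GrayImage(pixels=out, bit_depth=img.bit_depth)
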