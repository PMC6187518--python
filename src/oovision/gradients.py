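"""Per-pixel intensity gradients and thresholded edge extraction.

Conventions: ``x`` is the column index (increasing rightward), ``y`` the row
index (increasing downward).  ``gx`` and ``gy`` are the Sobel derivatives
along x and y; the orientation is ``atan2(gy, gx)`` so that
``cos(orientation) = gx/|∇f|`` and ``sin(orientation) = gy/|∇f|`` wherever
the magnitude is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import GrayImage, InvalidImageError


@dataclass
class GradientField:
    """Signed derivatives, magnitude and orientation on the image grid."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape  # type: ignore[return-value]


@dataclass
class EdgePointSet:
    """Pixels whose gradient magnitude clears a threshold.

    Coordinates are unique by construction (one entry per surviving pixel).
    """

    rows: np.ndarray
    cols: np.ndarray
    magnitudes: np.ndarray
    orientations: np.ndarray
    threshold_used: float

    def __len__(self) -> int:
        return self.rows.size


def compute_gradients(img: GrayImage) -> GradientField:
    """3×3 Sobel gradient field with edge-replicated borders.

    The magnitude is ``hypot(gx, gy)`` computed directly from the stored
    derivatives, so it can never drift from them.
    """
    if min(img.shape) < 3:
        raise InvalidImageError("image must be at least 3×3 for a 3×3 gradient operator")
    px = img.pixels
    gx = ndimage.sobel(px, axis=1, mode="nearest")
    gy = ndimage.sobel(px, axis=0, mode="nearest")
    magnitude = np.hypot(gx, gy)
    orientation = np.arctan2(gy, gx)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, orientation=orientation)


def threshold_edges(field: GradientField, gmag_threshold: float) -> EdgePointSet:
    """Return exactly the pixels whose magnitude is ≥ ``gmag_threshold``."""
    if gmag_threshold < 0:
        raise ValueError("gradient-magnitude threshold must be non-negative")
    rows, cols = np.nonzero(field.magnitude >= gmag_threshold)
    return EdgePointSet(
        rows=rows,
        cols=cols,
        magnitudes=field.magnitude[rows, cols],
        orientations=field.orientation[rows, cols],
        threshold_used=float(gmag_threshold),
    )


def auto_threshold(field: GradientField, keep_fraction: float = 0.10) -> float:
    """Magnitude quantile retaining at most ``keep_fraction`` of the
    nonzero-magnitude pixels.

    This bounds the edge-point count fed to the Hough stage, which is what
    keeps the vote affordable on large rasters.  With ``keep_fraction = 1``
    the smallest nonzero magnitude is returned; an all-zero field yields 0
    with a warning.  Ties at the cut move the threshold up to the next
    distinct value, except when the tied block extends to the maximum, in
    which case the whole block is kept (an empty edge set would be worse
    than a large one).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    nonzero = field.magnitude[field.magnitude > 0]
    if nonzero.size == 0:
        warnings.warn("all-zero gradient field: threshold defaults to 0", stacklevel=2)
        return 0.0
    n_keep = max(1, int(np.floor(keep_fraction * nonzero.size)))
    ordered = np.sort(nonzero)[::-1]
    thr = float(ordered[n_keep - 1])
    if int(np.count_nonzero(nonzero >= thr)) > n_keep:
        # ties at the cut: move up to the next distinct value so that at
        # most n_keep survive (unless the field is single-valued)
        higher = ordered[ordered > thr]
        if higher.size:
            thr = float(higher[-1])
    return thr
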