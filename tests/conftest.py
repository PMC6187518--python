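"""Shared fixtures and independent oracle implementations.

The oracles here (brute-force correlation, three-parameter Hough scan,
naive ellipse scorer) deliberately share no code with the package: they are
straight transcriptions of the definitions, used to pin expected values.
"""

from __future__ import annotations

import numpy as np
import pytest

from oovision.imaging import GrayImage


def draw_disc(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    fg: float = 200.0,
    bg: float = 50.0,
) -> np.ndarray:
    """Anti-aliased disc on a constant background (float intensities)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    d = np.hypot(rows - center[0], cols - center[1])
    inside = np.clip(radius - d + 0.5, 0.0, 1.0)
    return bg + (fg - bg) * inside


def draw_ellipse(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    fg: float = 200.0,
    bg: float = 50.0,
) -> np.ndarray:
    """Anti-aliased axis-aligned filled ellipse (a along cols, b along rows)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    rho = np.sqrt(((cols - center[1]) / a) ** 2 + ((rows - center[0]) / b) ** 2)
    inside = np.clip((1.0 - rho) * min(a, b) + 0.5, 0.0, 1.0)
    return bg + (fg - bg) * inside


def brute_correlate(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Direct double-loop 2-D correlation with edge replication."""
    h, w = pixels.shape
    k = mask.shape[0] // 2
    padded = np.pad(pixels, k, mode="edge")
    out = np.zeros_like(pixels, dtype=float)
    for r in range(h):
        for c in range(w):
            out[r, c] = float((padded[r : r + 2 * k + 1, c : c + 2 * k + 1] * mask).sum())
    return out


def brute_hough_center(
    rows: np.ndarray,
    cols: np.ndarray,
    image_shape: tuple[int, int],
    radii: np.ndarray,
) -> tuple[int, int]:
    """Unweighted exhaustive Hough over all (x0, y0, r) triples.

    For each candidate centre and radius, counts edge points whose distance
    to the centre is within half a pixel of the radius; returns the centre
    of the best (centre, radius) pair.
    """
    h, w = image_shape
    best = (-1, 0, 0)
    for r0 in range(h):
        d_row = (rows - r0) ** 2
        for c0 in range(w):
            d = np.sqrt(d_row + (cols - c0) ** 2)
            for r in radii:
                votes = int(np.count_nonzero(np.abs(d - r) <= 0.5))
                if votes > best[0]:
                    best = (votes, r0, c0)
    return best[1], best[2]


def naive_ellipse_scores(
    magnitude: np.ndarray,
    center: tuple[float, float],
    radii: np.ndarray,
    k: int,
) -> np.ndarray:
    """Independent (a, b) boundary-score surface with its own bilinear
    interpolation (zero outside the image)."""

    def bilinear(r: float, c: float) -> float:
        h, w = magnitude.shape
        if r < 0 or c < 0 or r > h - 1 or c > w - 1:
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            total = 0.0
            for dr in (0, 1):
                for dc in (0, 1):
                    rr, cc = r0 + dr, c0 + dc
                    wgt = (1 - abs(r - rr)) * (1 - abs(c - cc))
                    if 0 <= rr < h and 0 <= cc < w and wgt > 0:
                        total += wgt * magnitude[rr, cc]
            return total
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        r1, c1 = min(r0 + 1, magnitude.shape[0] - 1), min(c0 + 1, magnitude.shape[1] - 1)
        fr, fc = r - r0, c - c0
        return float(
            magnitude[r0, c0] * (1 - fr) * (1 - fc)
            + magnitude[r1, c0] * fr * (1 - fc)
            + magnitude[r0, c1] * (1 - fr) * fc
            + magnitude[r1, c1] * fr * fc
        )

    phi = np.linspace(0, 2 * np.pi, k, endpoint=False)
    scores = np.zeros((radii.size, radii.size))
    for i, a in enumerate(radii):
        for j, b in enumerate(radii):
            vals = [
                bilinear(center[0] + b * np.sin(p), center[1] + a * np.cos(p))
                for p in phi
            ]
            scores[i, j] = float(np.mean(vals))
    return scores


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180825)


@pytest.fixture
def gray_ramp() -> GrayImage:
    """Horizontal ramp: intensity grows with the column index."""
    cols = np.tile(np.arange(32, dtype=float) * 4.0, (32, 1))
    return GrayImage(pixels=cols)
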