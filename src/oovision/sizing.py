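"""Object sizing by axis-aligned elliptical fitting around a fixed centre.

The boundary model is ``x = x0 + a·cosφ, y = y0 + b·sinφ`` with no rotation
term.  For every semi-axis pair ``(a, b)`` on the discretised radius grid,
the candidate is scored by the mean gradient magnitude sampled (bilinear)
at equally spaced boundary points; the best-scoring pair is returned.  The
method needs no explicit edge identification, which is what makes it robust
on granular cell interiors, and it degrades gracefully to the circular fit
when ``a = b`` wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gradients import GradientField
from .hough import CenterEstimate, RadiusRange
from .imaging import InvalidConfigurationError


@dataclass
class EllipseParams:
    """An axis-aligned ellipse: centre, semi-axes and boundary score.

    ``a`` runs along x (columns), ``b`` along y (rows), both in pixels.
    ``score`` is the mean boundary gradient magnitude in intensity units.
    """

    row: float
    col: float
    a: float
    b: float
    score: float

    @property
    def center(self) -> tuple[float, float]:
        return self.row, self.col


def boundary_points(
    row: float, col: float, a: float, b: float, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """``k`` equally spaced (rows, cols) samples of the ellipse boundary."""
    phi = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    return row + b * np.sin(phi), col + a * np.cos(phi)


def _parabolic_offset(left: float, mid: float, right: float) -> float:
    """Sub-step offset of a quadratic through three equally spaced samples."""
    denom = left - 2.0 * mid + right
    if denom >= -1e-12:  # not a proper local maximum
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def fit_ellipse_axes(
    field: GradientField,
    center: CenterEstimate,
    rr: RadiusRange,
    refine: bool = True,
) -> EllipseParams | None:
    """Exhaustive (a, b) boundary-score scan around a fixed centre.

    The gradient magnitude is restricted to the square window of side
    ``2·r_max`` around the centre; ``K = max(64, ⌈2π·r_max⌉)`` boundary
    points (at least one per boundary pixel) are sampled bilinearly for each
    candidate pair.  Ties are broken by the smaller ``a + b``, then the
    smaller ``a``.  With ``refine`` the integer-grid optimum is polished by
    1-D parabolic interpolation of the score profile along each axis.

    Returns ``None`` when the window contains no gradient signal.
    """
    h, w = field.shape
    r0, c0 = center.row, center.col
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise InvalidConfigurationError(
            f"centre ({r0:.1f}, {c0:.1f}) outside image of shape {(h, w)}"
        )

    half = int(np.ceil(rr.r_max)) + 1
    rlo, rhi = max(int(r0) - half, 0), min(int(r0) + half + 1, h)
    clo, chi = max(int(c0) - half, 0), min(int(c0) + half + 1, w)
    window = field.magnitude[rlo:rhi, clo:chi]
    if not np.any(window > 0):
        return None
    mag = np.zeros_like(field.magnitude)
    mag[rlo:rhi, clo:chi] = window

    radii = rr.radii
    n = radii.size
    k = max(64, int(np.ceil(2.0 * np.pi * rr.r_max)))
    phi = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    cos_phi = np.cos(phi)
    sin_phi = np.sin(phi)

    scores = np.empty((n, n))
    rows_b = r0 + radii[:, None] * sin_phi[None, :]  # (n_b, k), shared across a
    for i, a in enumerate(radii):
        cols_a = c0 + a * cos_phi
        coords = np.stack(
            [rows_b.ravel(), np.broadcast_to(cols_a, (n, k)).ravel()]
        )
        vals = ndimage.map_coordinates(mag, coords, order=1, mode="constant", cval=0.0)
        scores[i] = vals.reshape(n, k).mean(axis=1)

    best = scores.max()
    ties_a, ties_b = np.nonzero(scores >= best - 1e-12)
    order = np.lexsort((radii[ties_a], radii[ties_a] + radii[ties_b]))
    ia, ib = int(ties_a[order[0]]), int(ties_b[order[0]])
    a_best = float(radii[ia])
    b_best = float(radii[ib])

    if refine and n >= 3:
        step = float(radii[1] - radii[0])
        if 0 < ia < n - 1:
            a_best += step * _parabolic_offset(
                scores[ia - 1, ib], scores[ia, ib], scores[ia + 1, ib]
            )
        if 0 < ib < n - 1:
            b_best += step * _parabolic_offset(
                scores[ia, ib - 1], scores[ia, ib], scores[ia, ib + 1]
            )
        a_best = float(np.clip(a_best, rr.r_min, rr.r_max))
        b_best = float(np.clip(b_best, rr.r_min, rr.r_max))

    return EllipseParams(row=r0, col=c0, a=a_best, b=b_best, score=float(scores[ia, ib]))


def equivalent_diameter(e: EllipseParams) -> float:
    """Diameter of the circle with the same area: ``2·√(a·b)`` pixels."""
    return 2.0 * float(np.sqrt(e.a * e.b))
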