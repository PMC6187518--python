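"""Gradient-weighted circular Hough voting and accumulator peak extraction.

Each edge point casts votes along its gradient line at every discretised
radius, at ``(x - r·cosθ, y - r·sinθ)`` and ``(x + r·cosθ, y + r·sinθ)``.
Both polarities are cast because the gradient sign flips between
bright-on-dark and dark-on-bright imaging, and microscope background colours
vary.  Every vote is weighted by the casting point's gradient magnitude, so
sharp edges dominate blurred ones.  The accumulator is 2-D over candidate
centres with the radius marginalised: sizing is a separate, later stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gradients import EdgePointSet
from .imaging import FilterMask

_PEAK_MASK = FilterMask.binomial(3)

#: Nominal thickness (px) of the gradient band a blurred object boundary
#: leaves in the thresholded edge set.  A band of thickness T casts ≈T²
#: times the vote mass of an ideal 1-px circle (T rings × T matching radius
#: steps), so the reference vote for confidence scales by T².
EDGE_BAND_PX = 4.5


@dataclass
class RadiusRange:
    """Candidate radius interval in pixels, discretised in ``n_steps``.

    The default discretisation is 1-px steps, ``n_steps = r_max − r_min + 1``.
    """

    r_min: float
    r_max: float
    n_steps: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= self.r_max:
            raise ValueError(f"need 0 < r_min <= r_max, got [{self.r_min}, {self.r_max}]")
        if self.n_steps is None:
            self.n_steps = int(round(self.r_max - self.r_min)) + 1
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")

    @property
    def radii(self) -> np.ndarray:
        if self.n_steps == 1:
            return np.array([0.5 * (self.r_min + self.r_max)])
        return np.linspace(self.r_min, self.r_max, self.n_steps)


@dataclass
class HoughAccumulator:
    """2-D vote surface over candidate centres.

    ``total_weight`` is the sum of all cells; ``mean_vote_weight`` the mean
    weight of the in-bounds votes actually cast, used to normalise peak
    confidence.  ``dir_x`` / ``dir_y``, when populated, hold the vector sum
    of vote weights along the unit direction from each cell towards its
    casting edge point.  A genuine circle centre collects votes from all
    around, so its vector sum cancels; votes focused from one side (e.g. a
    larger rim's offset ring) do not, and ``isotropic_votes`` discounts
    them.
    """

    votes: np.ndarray
    radius_range: RadiusRange
    total_weight: float = field(init=False)
    n_votes: int = 0
    mean_vote_weight: float = 0.0
    dir_x: np.ndarray | None = None
    dir_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.total_weight = float(self.votes.sum())

    def isotropic_votes(self) -> np.ndarray:
        """Per-cell vote mass converging from all directions:
        ``votes − ‖vector sum‖`` (non-negative by the triangle inequality).
        Falls back to the raw votes when directions were not tracked."""
        if self.dir_x is None or self.dir_y is None:
            return self.votes
        return self.votes - np.hypot(self.dir_x, self.dir_y)


@dataclass
class CenterEstimate:
    """A candidate object centre read off the accumulator.

    ``confidence`` is the background-corrected vote mass of the peak divided
    by the vote mass a full circle at ``r_min`` would deposit (perimeter ×
    mean vote weight × the squared nominal edge-band thickness); it is
    dimensionless and ≥ 0.  Values near or above 1 indicate a full, sharp
    circular boundary; the default detection gate is 0.25.
    """

    row: float
    col: float
    peak_vote: float
    confidence: float

    @property
    def center(self) -> tuple[float, float]:
        return self.row, self.col


def vote_circular(
    edges: EdgePointSet, rr: RadiusRange, image_shape: tuple[int, int]
) -> HoughAccumulator:
    """Cast gradient-weighted centre votes for every edge point and radius.

    Votes landing outside the image are discarded; each vote is binned to
    the nearest accumulator cell.
    """
    h, w = image_shape
    votes_flat = np.zeros(h * w)
    if len(edges) == 0:
        warnings.warn("empty edge set: accumulator is empty", stacklevel=2)
        acc = HoughAccumulator(votes=votes_flat.reshape(h, w), radius_range=rr)
        return acc

    x = edges.cols.astype(np.float64)
    y = edges.rows.astype(np.float64)
    cos_t = np.cos(edges.orientations)
    sin_t = np.sin(edges.orientations)
    weights = edges.magnitudes.astype(np.float64)

    dirx_flat = np.zeros(h * w)
    diry_flat = np.zeros(h * w)
    n_votes = 0
    weight_cast = 0.0
    for r in rr.radii:
        for sign in (-1.0, 1.0):
            cc = np.rint(x + sign * r * cos_t)
            rrow = np.rint(y + sign * r * sin_t)
            ok = (rrow >= 0) & (rrow < h) & (cc >= 0) & (cc < w)
            if not ok.any():
                continue
            flat = (rrow[ok] * w + cc[ok]).astype(np.intp)
            wk = weights[ok]
            votes_flat += np.bincount(flat, weights=wk, minlength=h * w)
            # unit direction from the landing cell back to the edge point
            dirx_flat += np.bincount(flat, weights=-sign * wk * cos_t[ok], minlength=h * w)
            diry_flat += np.bincount(flat, weights=-sign * wk * sin_t[ok], minlength=h * w)
            n_votes += int(ok.sum())
            weight_cast += float(wk.sum())

    acc = HoughAccumulator(
        votes=votes_flat.reshape(h, w),
        radius_range=rr,
        dir_x=dirx_flat.reshape(h, w),
        dir_y=diry_flat.reshape(h, w),
    )
    acc.n_votes = n_votes
    acc.mean_vote_weight = weight_cast / n_votes if n_votes else 0.0
    return acc


def _peak_estimate(
    acc: HoughAccumulator, allowed: np.ndarray | None
) -> CenterEstimate | None:
    h, w = acc.votes.shape
    if allowed is not None and not allowed.any():
        return None
    if not np.any(acc.votes > 0):
        return None
    votes = acc.isotropic_votes()

    smoothed = ndimage.correlate(votes, _PEAK_MASK.coefficients, mode="nearest")
    if allowed is None:
        search = smoothed
        searched_votes = votes
    else:
        search = np.where(allowed, smoothed, -np.inf)
        searched_votes = votes[allowed]
    if search.max() <= 0:
        return None
    # np.argmax scans in C order, so ties resolve to the smallest row, then
    # the smallest column — the documented tie-break.
    idx = int(np.argmax(search))
    row, col = divmod(idx, w)

    # The cluster around a true centre spreads roughly in proportion to the
    # radius (angular error of the edge orientation × r), so the mass window
    # grows with r_min; 3×3 at polar-body scale.
    hw = max(1, int(np.ceil(0.04 * acc.radius_range.r_min)))
    r0, r1 = max(row - hw, 0), min(row + hw + 1, h)
    c0, c1 = max(col - hw, 0), min(col + hw + 1, w)
    window_votes = votes[r0:r1, c0:c1]
    mass = float(window_votes.sum())

    # Background correction: concentric structures (e.g. the zona pellucida)
    # fill the searched region with a near-uniform vote plateau; subtracting
    # the per-cell median separates a genuine clustered peak from it.
    background = float(np.median(searched_votes))
    peak_vote = max(mass - window_votes.size * background, 0.0)

    # Sub-cell refinement: centroid of the smoothed 3×3 window around the
    # argmax ("maximum region"), exact for symmetric peaks.
    win = smoothed[r0:r1, c0:c1]
    wsum = float(win.sum())
    if wsum > 0:
        rows_idx, cols_idx = np.mgrid[r0:r1, c0:c1]
        row_f = float((win * rows_idx).sum() / wsum)
        col_f = float((win * cols_idx).sum() / wsum)
    else:
        row_f, col_f = float(row), float(col)

    denom = (
        2.0 * np.pi * acc.radius_range.r_min * acc.mean_vote_weight * EDGE_BAND_PX**2
    )
    confidence = peak_vote / denom if denom > 0 else 0.0
    return CenterEstimate(row=row_f, col=col_f, peak_vote=peak_vote, confidence=confidence)


def find_center(acc: HoughAccumulator) -> CenterEstimate | None:
    """Locate the accumulator peak after 3×3 binomial smoothing.

    Returns ``None`` (no-detection) for an all-zero accumulator.  Ties are
    broken by the smallest row, then the smallest column.
    """
    return _peak_estimate(acc, allowed=None)


def find_center_excluding(
    acc: HoughAccumulator, exclusion_mask: np.ndarray
) -> CenterEstimate | None:
    """Like :func:`find_center`, restricted to cells where
    ``exclusion_mask`` is False.

    Used to confine the polar-body search to the perivitelline annulus.
    Returns ``None`` when every cell is masked or no votes survive.
    """
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    if exclusion_mask.shape != acc.votes.shape:
        raise ValueError("exclusion mask must match the accumulator shape")
    return _peak_estimate(acc, allowed=~exclusion_mask)
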