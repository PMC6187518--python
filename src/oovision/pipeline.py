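"""End-to-end detection: oocyte first, then the polar body confined to the
perivitelline annulus, and the positional report.

The reported angle convention: image rows grow downward, so the y-term is
negated to make bearings counter-clockwise-positive from the +x axis (the
mathematical convention, with 90° pointing up in the displayed image).
Relative positions are expressed with respect to the image centre — the
centre of the microscope's vision field — and converted to micrometres when
a calibration is supplied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .gradients import EdgePointSet, GradientField, auto_threshold, compute_gradients, threshold_edges
from .hough import CenterEstimate, RadiusRange, find_center, find_center_excluding, vote_circular
from .imaging import FilterMask, RgbImage, contrast_enhance, to_grayscale, weighted_smooth
from .sizing import EllipseParams, equivalent_diameter, fit_ellipse_axes

POLAR_BODY_NOT_LOCATED = "polar body not located"


class UndefinedAngleError(ValueError):
    """The bearing between two coincident centres is undefined."""


@dataclass
class PipelineConfig:
    """Tunable detector parameters.

    ``mask_size`` selects the 3×3 or 5×5 weighted-average smoothing mask;
    ``keep_fraction`` bounds the edge-point count passed to the Hough vote;
    ``min_confidence`` gates whether an accumulator peak counts as a
    detection (it implements the "polar body not located" branch);
    ``annulus_inner_factor`` (fraction of the fitted rim) and
    ``annulus_outer_pb_radii`` (padding beyond the rim in polar-body r_max
    units) bound the perivitelline search annulus.
    """

    mask_size: int = 5
    keep_fraction: float = 0.10
    min_confidence: float = 0.25
    annulus_inner_factor: float = 0.95
    annulus_outer_pb_radii: float = 3.0
    refine_fit: bool = True

    def smoothing_mask(self) -> FilterMask:
        return FilterMask.binomial(self.mask_size)


@dataclass
class Calibration:
    """Micrometres per pixel; absent calibration keeps the report in px."""

    um_per_px: float
    provided: bool = True

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")


@dataclass
class Detection:
    """One detected (or undetected) object."""

    found: bool
    center_px: tuple[float, float] | None = None
    ellipse: EllipseParams | None = None
    diameter_px: float | None = None
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if not self.found:
            self.ellipse = None
            self.diameter_px = None


@dataclass
class DetectionReport:
    """Full positional report for one micrograph."""

    oocyte: Detection
    polar_body: Detection
    angle_deg: float | None
    image_center_px: tuple[float, float]
    calibration: Calibration | None = None
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        s = self.calibration.um_per_px if self.calibration else None

        def obj(d: Detection) -> dict[str, Any]:
            out: dict[str, Any] = {"found": bool(d.found), "confidence": round(float(d.confidence), 6)}
            if d.found and d.center_px is not None:
                r, c = d.center_px
                out["center_px"] = [round(r, 3), round(c, 3)]
                if s is not None:
                    cr, cc = self.image_center_px
                    out["center_um_rel"] = [
                        round((c - cc) * s, 3),
                        round(-(r - cr) * s, 3),
                    ]
                if d.ellipse is not None:
                    out["a_px"] = round(d.ellipse.a, 3)
                    out["b_px"] = round(d.ellipse.b, 3)
                if d.diameter_px is not None:
                    out["diameter_px"] = round(d.diameter_px, 3)
                    if s is not None:
                        out["diameter_um"] = round(d.diameter_px * s, 3)
            return out

        return {
            "oocyte": obj(self.oocyte),
            "polar_body": obj(self.polar_body),
            "angle_deg": None if self.angle_deg is None else round(self.angle_deg, 3),
            "image_center_px": [self.image_center_px[0], self.image_center_px[1]],
            "calibration": {"um_per_px": s, "provided": self.calibration.provided}
            if self.calibration
            else None,
            "messages": list(self.messages),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class _Preprocessed:
    """Shared intermediate state so both objects reuse one gradient pass."""

    field: GradientField
    edges: EdgePointSet


def preprocess(img: RgbImage, cfg: PipelineConfig) -> _Preprocessed:
    """Grayscale → contrast stretch → weighted smoothing → gradients → edges."""
    gray = to_grayscale(img)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant image: stretch is a no-op
        enhanced = contrast_enhance(gray)
    smoothed = weighted_smooth(enhanced, cfg.smoothing_mask())
    gfield = compute_gradients(smoothed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr = auto_threshold(gfield, cfg.keep_fraction)
    edges = threshold_edges(gfield, thr) if thr > 0 else threshold_edges(gfield, np.inf)
    return _Preprocessed(field=gfield, edges=edges)


def _detect(
    pre: _Preprocessed,
    rr: RadiusRange,
    cfg: PipelineConfig,
    exclusion_mask: np.ndarray | None,
) -> Detection:
    if len(pre.edges) == 0:
        return Detection(found=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc = vote_circular(pre.edges, rr, pre.field.shape)
    if exclusion_mask is None:
        est = find_center(acc)
    else:
        est = find_center_excluding(acc, exclusion_mask)
    if est is None:
        return Detection(found=False)
    if est.confidence < cfg.min_confidence:
        return Detection(found=False, center_px=est.center, confidence=est.confidence)
    ellipse = fit_ellipse_axes(pre.field, est, rr, refine=cfg.refine_fit)
    if ellipse is None:
        return Detection(found=False, center_px=est.center, confidence=est.confidence)
    return Detection(
        found=True,
        center_px=est.center,
        ellipse=ellipse,
        diameter_px=equivalent_diameter(ellipse),
        confidence=est.confidence,
    )


def detect_oocyte(
    img: RgbImage,
    rr_oocyte: RadiusRange,
    cfg: PipelineConfig | None = None,
    pre: _Preprocessed | None = None,
) -> Detection:
    """Run the full stage chain for the oocyte."""
    cfg = cfg or PipelineConfig()
    if pre is None:
        pre = preprocess(img, cfg)
    return _detect(pre, rr_oocyte, cfg, exclusion_mask=None)


def perivitelline_mask(
    image_shape: tuple[int, int],
    oocyte: Detection,
    rr_pb: RadiusRange,
    cfg: PipelineConfig,
) -> np.ndarray:
    """Exclusion mask keeping only the perivitelline annulus around the
    oocyte rim.

    Bounds are expressed in the fitted ellipse's normalised radius so the
    annulus tracks the rim of elliptical oocytes: cells are admitted when
    they lie outside ``inner_factor`` × the fitted rim and inside the rim
    padded by ``outer_pb_radii`` × the polar-body r_max on both axes.  The
    tight inner bound keeps ooplasm granularity — which otherwise casts
    clustered votes just inside the rim — out of the polar-body search; the
    outer margin admits polar bodies pressed against the zona pellucida.
    """
    assert oocyte.found and oocyte.center_px is not None and oocyte.ellipse is not None
    h, w = image_shape
    rows, cols = np.mgrid[0:h, 0:w]
    e = oocyte.ellipse
    dr = rows - oocyte.center_px[0]
    dc = cols - oocyte.center_px[1]
    rho_rim = np.sqrt((dc / e.a) ** 2 + (dr / e.b) ** 2)
    pad = cfg.annulus_outer_pb_radii * rr_pb.r_max
    rho_outer = np.sqrt((dc / (e.a + pad)) ** 2 + (dr / (e.b + pad)) ** 2)
    return (rho_rim < cfg.annulus_inner_factor) | (rho_outer > 1.0)


def _annulus_edges(
    edges: EdgePointSet, oocyte: Detection, rr_pb: RadiusRange, cfg: PipelineConfig
) -> EdgePointSet:
    """Edge points that can belong to a perivitelline-space object.

    The polar-body boundary lies outside the oolemma, so edge points inside
    ``annulus_inner_factor`` × the fitted rim are dropped before voting —
    otherwise ooplasm granularity casts votes that land beyond the rim and
    mimic a small-circle centre.  Points too far outside the padded annulus
    to reach any admissible centre are dropped as well.
    """
    e = oocyte.ellipse
    assert e is not None and oocyte.center_px is not None
    dr = edges.rows - oocyte.center_px[0]
    dc = edges.cols - oocyte.center_px[1]
    rho_rim = np.sqrt((dc / e.a) ** 2 + (dr / e.b) ** 2)
    pad = (cfg.annulus_outer_pb_radii + 1.0) * rr_pb.r_max
    rho_outer = np.sqrt((dc / (e.a + pad)) ** 2 + (dr / (e.b + pad)) ** 2)
    keep = (rho_rim >= cfg.annulus_inner_factor) & (rho_outer <= 1.0)
    return EdgePointSet(
        rows=edges.rows[keep],
        cols=edges.cols[keep],
        magnitudes=edges.magnitudes[keep],
        orientations=edges.orientations[keep],
        threshold_used=edges.threshold_used,
    )


def detect_polar_body(
    img: RgbImage,
    rr_pb: RadiusRange,
    oocyte: Detection,
    cfg: PipelineConfig | None = None,
    pre: _Preprocessed | None = None,
) -> Detection:
    """Detect the polar body inside the perivitelline annulus.

    Requires a found oocyte; returns ``found=False`` when no confident peak
    exists in the annulus (the "polar body not located" branch).
    """
    cfg = cfg or PipelineConfig()
    if not oocyte.found:
        raise ValueError("polar-body detection requires a found oocyte")
    if pre is None:
        pre = preprocess(img, cfg)
    mask = perivitelline_mask(pre.field.shape, oocyte, rr_pb, cfg)
    pre_pb = _Preprocessed(
        field=pre.field, edges=_annulus_edges(pre.edges, oocyte, rr_pb, cfg)
    )
    return _detect(pre_pb, rr_pb, cfg, exclusion_mask=mask)


def orientation_angle(
    oocyte_center: tuple[float, float], pb_center: tuple[float, float]
) -> float:
    """Bearing of the polar body from the oocyte centre, degrees in [0, 360).

    Measured counter-clockwise from the +x axis with y pointing up, i.e.
    ``atan2(-(Δrow), Δcol)``.
    """
    drow = pb_center[0] - oocyte_center[0]
    dcol = pb_center[1] - oocyte_center[1]
    if drow == 0 and dcol == 0:
        raise UndefinedAngleError("coincident centres have no bearing")
    return float(np.degrees(np.arctan2(-drow, dcol)) % 360.0)


def build_report(
    oocyte: Detection,
    polar_body: Detection,
    image_shape: tuple[int, int],
    calib: Calibration | None = None,
) -> DetectionReport:
    """Assemble the positional report.

    The image centre — the reference point of the microscope's vision field
    — is ``((H−1)/2, (W−1)/2)``.  The bearing angle is present iff both
    objects were found.
    """
    h, w = image_shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    messages: list[str] = []
    angle = None
    if oocyte.found and polar_body.found:
        angle = orientation_angle(oocyte.center_px, polar_body.center_px)  # type: ignore[arg-type]
    elif oocyte.found and not polar_body.found:
        messages.append(POLAR_BODY_NOT_LOCATED)
    elif not oocyte.found:
        messages.append("oocyte not located")
    return DetectionReport(
        oocyte=oocyte,
        polar_body=polar_body,
        angle_deg=angle,
        image_center_px=center,
        calibration=calib,
        messages=messages,
    )


def analyze_image(
    img: RgbImage,
    rr_oocyte: RadiusRange,
    rr_pb: RadiusRange,
    cfg: PipelineConfig | None = None,
    calib: Calibration | None = None,
) -> DetectionReport:
    """One-shot detection of both objects sharing a single gradient pass."""
    cfg = cfg or PipelineConfig()
    pre = preprocess(img, cfg)
    oocyte = detect_oocyte(img, rr_oocyte, cfg, pre=pre)
    if oocyte.found:
        pb = detect_polar_body(img, rr_pb, oocyte, cfg, pre=pre)
    else:
        pb = Detection(found=False)
    return build_report(oocyte, pb, pre.field.shape, calib)


def draw_overlay(img: RgbImage, report: DetectionReport, path) -> None:
    """Write an annotated PNG: fitted boundaries, image-centre axes and the
    oocyte→polar-body bearing line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    h, w = img.shape
    fig, ax = plt.subplots(figsize=(6, 6 * h / w))
    ax.imshow(np.clip(img.pixels, 0, 255).astype(np.uint8))
    cr, cc = report.image_center_px
    ax.axhline(cr, color="red", lw=0.8)
    ax.axvline(cc, color="red", lw=0.8)
    for det, color in ((report.oocyte, "deepskyblue"), (report.polar_body, "orange")):
        if det.found and det.ellipse is not None:
            e = det.ellipse
            ax.add_patch(
                MplEllipse(
                    (e.col, e.row), 2 * e.a, 2 * e.b, fill=False, color=color, lw=1.5
                )
            )
    if report.angle_deg is not None:
        (orow, ocol) = report.oocyte.center_px  # type: ignore[misc]
        (prow, pcol) = report.polar_body.center_px  # type: ignore[misc]
        ax.plot([ocol, pcol], [orow, prow], color="lime", lw=1.5)
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
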