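"""Seeded generator of ground-truthed ICSI micrograph look-alikes and the
benchmark harness that scores the detector against the truth.

A scene is a denudated metaphase-II oocyte (ooplasm of ~140 µm equivalent
diameter with multiplicative granular texture), its perivitelline space,
the zona pellucida ring, and optionally a ~20 µm polar body inside the
perivitelline gap, rendered over an arbitrary background colour, then
Gaussian-blurred and corrupted with additive Gaussian noise.  Optional
cumulus-like clutter blobs near the zona emulate incomplete denudation.

The rendered perivitelline gap (default 24 µm) is wider than the
physiological one so the polar body fits wholly inside it, and so the zona
edges stay outside the user-supplied oocyte radius range; see the methods
note.  All randomness flows from the spec's seed: identical (spec, seed)
pairs render identical images.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .hough import RadiusRange
from .imaging import RgbImage, save_png
from .pipeline import Calibration, Detection, DetectionReport, PipelineConfig, analyze_image

DEFAULT_UM_PER_PX = 0.5
#: radius ranges a practitioner would supply, µm (oocyte ~140 µm diameter,
#: polar body ~20 µm diameter, with literature-scale slack)
OOCYTE_RANGE_UM = (55.0, 85.0)
POLAR_BODY_RANGE_UM = (5.0, 15.0)

CATEGORIES = ("background", "orientation", "magnification", "disturbance")


class InvalidSpecError(ValueError):
    """Scene description violating a geometric invariant."""


@dataclass
class OocyteGeom:
    """Oocyte placement and appearance, in µm relative to the image centre
    (x right, y up)."""

    center_um: tuple[float, float] = (0.0, 0.0)
    a_um: float = 70.0
    b_um: float = 70.0
    rim_contrast: float = 60.0
    granularity: float = 10.0


@dataclass
class PolarBodyGeom:
    """Polar-body placement inside the perivitelline gap.

    ``radial_frac`` ∈ [0, 1] slides the body from touching the oolemma to
    touching the zona; ``bearing_deg`` is counter-clockwise from +x (y up).
    """

    present: bool = True
    bearing_deg: float = 30.0
    radial_frac: float = 0.5
    a_um: float = 10.0
    b_um: float = 10.0
    rim_contrast: float = 55.0


@dataclass
class ClutterGeom:
    """Cumulus-like dark blobs near the zona pellucida."""

    count: int = 0
    size_um: tuple[float, float] = (8.0, 24.0)  # blob diameters
    contrast: float = 45.0


@dataclass
class SceneSpec:
    """Complete, seeded description of one synthetic micrograph.

    ``image_size=None`` auto-sizes the raster so the zona pellucida fits
    with at least a 10 px margin at the requested scale.
    """

    image_size: tuple[int, int] | None = None
    background_rgb: tuple[int, int, int] = (168, 158, 148)
    um_per_px: float = DEFAULT_UM_PER_PX
    oocyte: OocyteGeom = field(default_factory=OocyteGeom)
    polar_body: PolarBodyGeom = field(default_factory=PolarBodyGeom)
    pvs_gap_um: float = 24.0
    zona_um: float = 16.0
    blur_sigma: float = 1.5
    noise_sigma: float = 3.0
    clutter: ClutterGeom = field(default_factory=ClutterGeom)
    seed: int = 0

    @property
    def outer_radius_um(self) -> float:
        return max(self.oocyte.a_um, self.oocyte.b_um) + self.pvs_gap_um + self.zona_um

    def resolved_size(self) -> tuple[int, int]:
        if self.image_size is not None:
            return self.image_size
        off = max(abs(self.oocyte.center_um[0]), abs(self.oocyte.center_um[1]))
        margin_px = 24 + int(np.ceil(off / self.um_per_px))
        side = 2 * int(np.ceil(self.outer_radius_um / self.um_per_px)) + 2 * margin_px
        return side, side

    def validate(self) -> None:
        pb = self.polar_body
        if pb.present:
            r_pb = max(pb.a_um, pb.b_um)
            if self.pvs_gap_um < 2 * r_pb:
                raise InvalidSpecError(
                    "polar body does not fit wholly inside the perivitelline gap"
                )
        h, w = self.resolved_size()
        s = self.um_per_px
        off = max(abs(self.oocyte.center_um[0]), abs(self.oocyte.center_um[1])) / s
        if self.outer_radius_um / s + off + 10 > min(h, w) / 2:
            raise InvalidSpecError("oocyte does not fit in the image with a 10 px margin")


@dataclass
class SceneTruth:
    """Exact ground truth for one rendered scene (px and µm)."""

    um_per_px: float
    image_size: tuple[int, int]
    oocyte_center_px: tuple[float, float]
    oocyte_axes_px: tuple[float, float]
    oocyte_diameter_um: float
    pb_present: bool
    pb_center_px: tuple[float, float] | None
    pb_axes_px: tuple[float, float] | None
    pb_diameter_um: float | None
    pb_bearing_deg: float | None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _soft_ellipse(
    rows: np.ndarray, cols: np.ndarray, r0: float, c0: float, a: float, b: float
) -> np.ndarray:
    """Anti-aliased inside-indicator of an axis-aligned ellipse (~1 px ramp)."""
    rho = np.sqrt(((cols - c0) / a) ** 2 + ((rows - r0) / b) ** 2)
    width = 1.0 / min(a, b)  # ≈1 px expressed in normalised radius
    return np.clip((1.0 - rho) / width + 0.5, 0.0, 1.0)


def render_scene(spec: SceneSpec) -> tuple[RgbImage, SceneTruth]:
    """Render a scene and its exact ground truth.

    Deterministic: the same (spec, seed) always yields the same image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.resolved_size()
    s = spec.um_per_px
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0

    oo = spec.oocyte
    r0 = cr - oo.center_um[1] / s
    c0 = cc + oo.center_um[0] / s
    a_px, b_px = oo.a_um / s, oo.b_um / s
    gap_px = spec.pvs_gap_um / s
    zona_px = spec.zona_um / s

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    w_zona = _soft_ellipse(rows, cols, r0, c0, a_px + gap_px + zona_px, b_px + gap_px + zona_px)
    w_pvs = _soft_ellipse(rows, cols, r0, c0, a_px + gap_px, b_px + gap_px)
    w_oo = _soft_ellipse(rows, cols, r0, c0, a_px, b_px)

    # luminance offsets relative to the background: translucent zona (+8),
    # bright perivitelline gap (+10 more), ooplasm darker by rim_contrast
    delta = 8.0 * w_zona + 10.0 * w_pvs - oo.rim_contrast * w_oo

    # band-limited multiplicative granularity inside the ooplasm (what the
    # weighted-average filter exists to suppress)
    if oo.granularity > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=max(1.5 / s, 1.0))
        tex /= max(tex.std(), 1e-9)
        delta += oo.granularity * tex * w_oo

    pb = spec.polar_body
    pb_center_px = pb_axes_px = None
    pb_diam_um = pb_bearing = None
    if pb.present:
        r_pb_um = max(pb.a_um, pb.b_um)
        d_lo = max(oo.a_um, oo.b_um) + r_pb_um
        d_hi = max(oo.a_um, oo.b_um) + spec.pvs_gap_um - r_pb_um
        d_um = d_lo + pb.radial_frac * (d_hi - d_lo)
        theta = np.radians(pb.bearing_deg)
        pr = r0 - (d_um / s) * np.sin(theta)
        pc = c0 + (d_um / s) * np.cos(theta)
        w_pb = _soft_ellipse(rows, cols, pr, pc, pb.a_um / s, pb.b_um / s)
        delta -= pb.rim_contrast * w_pb
        pb_center_px = (float(pr), float(pc))
        pb_axes_px = (pb.a_um / s, pb.b_um / s)
        pb_diam_um = 2.0 * float(np.sqrt(pb.a_um * pb.b_um))
        pb_bearing = float(pb.bearing_deg % 360.0)

    cl = spec.clutter
    for _ in range(cl.count):
        bearing = rng.uniform(0, 2 * np.pi)
        d_um = rng.uniform(
            max(oo.a_um, oo.b_um) + spec.pvs_gap_um,
            spec.outer_radius_um + 12.0,
        )
        radius_px = 0.5 * rng.uniform(*cl.size_um) / s
        br = r0 - (d_um / s) * np.sin(bearing)
        bc = c0 + (d_um / s) * np.cos(bearing)
        br = float(np.clip(br, radius_px + 2, h - radius_px - 3))
        bc = float(np.clip(bc, radius_px + 2, w - radius_px - 3))
        delta -= cl.contrast * _soft_ellipse(rows, cols, br, bc, radius_px, radius_px)

    img = np.empty((h, w, 3))
    for ch in range(3):
        img[:, :, ch] = spec.background_rgb[ch] + delta
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255)

    truth = SceneTruth(
        um_per_px=s,
        image_size=(h, w),
        oocyte_center_px=(float(r0), float(c0)),
        oocyte_axes_px=(float(a_px), float(b_px)),
        oocyte_diameter_um=2.0 * float(np.sqrt(oo.a_um * oo.b_um)),
        pb_present=pb.present,
        pb_center_px=pb_center_px,
        pb_axes_px=pb_axes_px,
        pb_diameter_um=pb_diam_um,
        pb_bearing_deg=pb_bearing,
    )
    return RgbImage(pixels=img), truth


def _scene_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % 2**31)


def generate_suite(category: str, n: int, base_seed: int = 0) -> list[SceneSpec]:
    """Deterministic suite of scene specs for one experimental category.

    ``background``: distinct background colours, fixed clean geometry.
    ``orientation``: polar-body bearings evenly spanning [0, 360), small
    random oocyte offsets.  ``magnification``: scale factors spanning
    [0.5×, 2×] of the default µm/px with constant µm geometry.
    ``disturbance``: 5–20 cumulus-like blobs near the zona.
    """
    if n < 1:
        raise ValueError("suite size must be at least 1")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 97]))
    specs: list[SceneSpec] = []
    for i in range(n):
        seed = _scene_seed(base_seed, i)
        if category == "background":
            # distinct hues at detection-friendly luminance
            hue = i / n
            lum = 110 + 70 * ((i * 7) % n) / max(n - 1, 1)
            rgb = tuple(
                int(np.clip(lum * (0.75 + 0.5 * np.cos(2 * np.pi * (hue + k / 3.0))), 40, 230))
                for k in range(3)
            )
            specs.append(SceneSpec(background_rgb=rgb, seed=seed))
        elif category == "orientation":
            bearing = 360.0 * i / n
            offset = tuple(rng.uniform(-8.0, 8.0, size=2))
            specs.append(
                SceneSpec(
                    oocyte=OocyteGeom(center_um=offset),
                    polar_body=PolarBodyGeom(bearing_deg=bearing, radial_frac=float(rng.uniform(0.2, 0.8))),
                    seed=seed,
                )
            )
        elif category == "magnification":
            factor = 0.5 + 1.5 * i / max(n - 1, 1)
            specs.append(
                SceneSpec(
                    um_per_px=DEFAULT_UM_PER_PX * factor,
                    polar_body=PolarBodyGeom(bearing_deg=float(rng.uniform(0, 360))),
                    seed=seed,
                )
            )
        else:  # disturbance
            specs.append(
                SceneSpec(
                    polar_body=PolarBodyGeom(bearing_deg=float(rng.uniform(0, 360))),
                    clutter=ClutterGeom(count=int(rng.integers(5, 21))),
                    seed=seed,
                )
            )
    return specs


@dataclass
class BenchmarkResult:
    """Per-scene scores and aggregate detection/error statistics."""

    scenes: pd.DataFrame
    aggregate: dict[str, float]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scenes.to_csv(out / "benchmark_scenes.csv", index=False)
        (out / "benchmark_aggregate.json").write_text(
            json.dumps(self.aggregate, indent=2, sort_keys=True)
        )


def _center_error_px(
    det: Detection, truth_center: tuple[float, float] | None
) -> float:
    if not det.found or det.center_px is None or truth_center is None:
        return float("nan")
    return float(np.hypot(det.center_px[0] - truth_center[0], det.center_px[1] - truth_center[1]))


def default_detector(
    img: RgbImage, truth: SceneTruth, cfg: PipelineConfig
) -> DetectionReport:
    """Run the full pipeline with µm radius ranges converted at the scene
    scale (the ``truth`` argument supplies only the calibration)."""
    s = truth.um_per_px
    rr_oo = RadiusRange(OOCYTE_RANGE_UM[0] / s, OOCYTE_RANGE_UM[1] / s)
    rr_pb = RadiusRange(POLAR_BODY_RANGE_UM[0] / s, POLAR_BODY_RANGE_UM[1] / s)
    return analyze_image(img, rr_oo, rr_pb, cfg, calib=Calibration(um_per_px=s))


def run_benchmark(
    suite: list[SceneSpec],
    cfg: PipelineConfig | None = None,
    detector: Callable[[RgbImage, SceneTruth, PipelineConfig], DetectionReport] | None = None,
) -> BenchmarkResult:
    """Render every scene, run the detector and score it against the truth.

    A correct detection requires the reported centre to lie within 25% of
    the object's true diameter of the true centre.  Errors are aggregated
    over correctly detected scenes only; per-scene failures are recorded,
    never raised.
    """
    if not suite:
        raise ValueError("benchmark suite is empty")
    cfg = cfg or PipelineConfig()
    detector = detector or default_detector
    records: list[dict[str, Any]] = []
    for i, spec in enumerate(suite):
        img, truth = render_scene(spec)
        t0 = time.perf_counter()
        try:
            report = detector(img, truth, cfg)
        except Exception as exc:  # scored as a miss, not raised
            records.append(
                {
                    "scene": i, "um_per_px": truth.um_per_px, "error": str(exc),
                    "oocyte_detected": False, "oocyte_correct": False,
                    "oocyte_center_err_um": float("nan"), "oocyte_diam_err_pct": float("nan"),
                    "pb_present": truth.pb_present, "pb_detected": False, "pb_correct": False,
                    "pb_center_err_um": float("nan"), "pb_diam_err_pct": float("nan"),
                    "angle_deg": None, "runtime_s": time.perf_counter() - t0,
                }
            )
            continue
        runtime = time.perf_counter() - t0
        s = truth.um_per_px

        oo_err_px = _center_error_px(report.oocyte, truth.oocyte_center_px)
        oo_diam_true_px = truth.oocyte_diameter_um / s
        oo_correct = bool(
            report.oocyte.found and oo_err_px <= 0.25 * oo_diam_true_px
        )
        oo_diam_err_pct = (
            abs(report.oocyte.diameter_px - oo_diam_true_px) / oo_diam_true_px * 100.0
            if oo_correct
            else float("nan")
        )

        if truth.pb_present:
            pb_err_px = _center_error_px(report.polar_body, truth.pb_center_px)
            pb_diam_true_px = truth.pb_diameter_um / s  # type: ignore[operator]
            pb_correct = bool(
                report.polar_body.found and pb_err_px <= 0.25 * pb_diam_true_px
            )
            pb_diam_err_pct = (
                abs(report.polar_body.diameter_px - pb_diam_true_px) / pb_diam_true_px * 100.0
                if pb_correct
                else float("nan")
            )
        else:
            pb_err_px = float("nan")
            pb_correct = not report.polar_body.found
            pb_diam_err_pct = float("nan")

        records.append(
            {
                "scene": i,
                "um_per_px": s,
                "oocyte_detected": bool(report.oocyte.found),
                "oocyte_correct": oo_correct,
                "oocyte_center_err_um": oo_err_px * s if oo_correct else float("nan"),
                "oocyte_diam_err_pct": oo_diam_err_pct,
                "pb_present": truth.pb_present,
                "pb_detected": bool(report.polar_body.found),
                "pb_correct": pb_correct,
                "pb_center_err_um": pb_err_px * s if (truth.pb_present and pb_correct) else float("nan"),
                "pb_diam_err_pct": pb_diam_err_pct,
                "angle_deg": report.angle_deg,
                "runtime_s": runtime,
            }
        )

    df = pd.DataFrame.from_records(records)
    n = len(df)
    with_pb = df[df["pb_present"].astype(bool)]
    agg = {
        "n_scenes": float(n),
        "oocyte_detection_rate_pct": 100.0 * df["oocyte_correct"].sum() / n,
        "pb_detection_rate_pct": (
            100.0 * with_pb["pb_correct"].sum() / len(with_pb) if len(with_pb) else float("nan")
        ),
        "both_detection_rate_pct": (
            100.0 * (df["oocyte_correct"] & df["pb_correct"]).sum() / n
        ),
        "oocyte_diam_err_pct_max": float(np.nanmax(df["oocyte_diam_err_pct"])) if df["oocyte_diam_err_pct"].notna().any() else float("nan"),
        "oocyte_diam_err_pct_mean": float(np.nanmean(df["oocyte_diam_err_pct"])) if df["oocyte_diam_err_pct"].notna().any() else float("nan"),
        "pb_diam_err_pct_max": float(np.nanmax(df["pb_diam_err_pct"])) if df["pb_diam_err_pct"].notna().any() else float("nan"),
        "pb_diam_err_pct_mean": float(np.nanmean(df["pb_diam_err_pct"])) if df["pb_diam_err_pct"].notna().any() else float("nan"),
        "oocyte_center_err_um_max": float(np.nanmax(df["oocyte_center_err_um"])) if df["oocyte_center_err_um"].notna().any() else float("nan"),
        "oocyte_center_err_um_mean": float(np.nanmean(df["oocyte_center_err_um"])) if df["oocyte_center_err_um"].notna().any() else float("nan"),
        "pb_center_err_um_max": float(np.nanmax(df["pb_center_err_um"])) if df["pb_center_err_um"].notna().any() else float("nan"),
        "pb_center_err_um_mean": float(np.nanmean(df["pb_center_err_um"])) if df["pb_center_err_um"].notna().any() else float("nan"),
        "runtime_s_mean": float(df["runtime_s"].mean()),
    }
    return BenchmarkResult(scenes=df, aggregate=agg)


def write_scene_files(specs: list[SceneSpec], out_dir: str | Path) -> list[Path]:
    """Render and write each scene as PNG plus a sidecar truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, spec in enumerate(specs):
        img, truth = render_scene(spec)
        png = out / f"scene_{i:03d}.png"
        save_png(png, img.pixels)
        (out / f"scene_{i:03d}.truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True)
        )
        paths.append(png)
    return paths
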