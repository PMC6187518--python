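"""Scene generator determinism, geometry invariants and benchmark harness."""

import numpy as np
import pandas as pd
import pytest

from oovision.pipeline import Calibration, Detection, build_report
from oovision.sizing import EllipseParams
from oovision.synthetic import (
    ClutterGeom,
    InvalidSpecError,
    OocyteGeom,
    PolarBodyGeom,
    SceneSpec,
    generate_suite,
    render_scene,
    run_benchmark,
)


class TestRenderScene:
    def test_reproducible_from_spec_and_seed(self):
        spec = SceneSpec(seed=11, clutter=ClutterGeom(count=4))
        img1, t1 = render_scene(spec)
        img2, t2 = render_scene(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1 == t2

    def test_different_seeds_same_truth(self):
        img1, t1 = render_scene(SceneSpec(seed=1))
        img2, t2 = render_scene(SceneSpec(seed=2))
        assert not np.array_equal(img1.pixels, img2.pixels)
        assert t1 == t2

    def test_oocyte_darker_than_background(self):
        img, truth = render_scene(SceneSpec(seed=3, blur_sigma=0, noise_sigma=0))
        r, c = (int(round(v)) for v in truth.oocyte_center_px)
        assert img.pixels[r, c].mean() < np.mean(SceneSpec().background_rgb)

    def test_polar_body_inside_perivitelline_gap(self):
        spec = SceneSpec(seed=4, polar_body=PolarBodyGeom(radial_frac=1.0))
        _, truth = render_scene(spec)
        d = np.hypot(
            truth.pb_center_px[0] - truth.oocyte_center_px[0],
            truth.pb_center_px[1] - truth.oocyte_center_px[1],
        )
        r_pb = max(truth.pb_axes_px)
        gap_px = spec.pvs_gap_um / spec.um_per_px
        assert d - r_pb >= truth.oocyte_axes_px[0] - 1e-6
        assert d + r_pb <= truth.oocyte_axes_px[0] + gap_px + 1e-6

    def test_oversized_polar_body_rejected(self):
        spec = SceneSpec(polar_body=PolarBodyGeom(a_um=15.0, b_um=15.0))  # gap is 24 um
        with pytest.raises(InvalidSpecError):
            render_scene(spec)

    def test_oocyte_must_fit_with_margin(self):
        spec = SceneSpec(image_size=(300, 300))  # outer zona needs ~440 px
        with pytest.raises(InvalidSpecError):
            render_scene(spec)

    def test_truth_round_trips_through_report_coordinates(self):
        spec = SceneSpec(seed=9, oocyte=OocyteGeom(center_um=(7.0, -4.0)))
        _, truth = render_scene(spec)
        det = Detection(
            found=True,
            center_px=truth.oocyte_center_px,
            ellipse=EllipseParams(
                row=truth.oocyte_center_px[0], col=truth.oocyte_center_px[1],
                a=truth.oocyte_axes_px[0], b=truth.oocyte_axes_px[1], score=1.0,
            ),
            diameter_px=truth.oocyte_diameter_um / truth.um_per_px,
            confidence=1.0,
        )
        rep = build_report(det, Detection(found=False), truth.image_size, Calibration(truth.um_per_px))
        x_um, y_um = rep.to_dict()["oocyte"]["center_um_rel"]
        assert x_um == pytest.approx(7.0, abs=0.5 * truth.um_per_px)
        assert y_um == pytest.approx(-4.0, abs=0.5 * truth.um_per_px)


class TestGenerateSuite:
    def test_orientation_bearings_evenly_spaced(self):
        specs = generate_suite("orientation", 8, base_seed=1)
        bearings = [s.polar_body.bearing_deg for s in specs]
        assert bearings == [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]

    def test_same_base_seed_reproduces_specs(self):
        assert generate_suite("background", 6, 5) == generate_suite("background", 6, 5)

    def test_background_colors_distinct(self):
        colors = {s.background_rgb for s in generate_suite("background", 20, 3)}
        assert len(colors) == 20

    def test_magnification_varies_scale_not_micron_truth(self):
        specs = generate_suite("magnification", 3, base_seed=2)
        scales = [s.um_per_px for s in specs]
        assert len(set(scales)) == 3
        assert min(scales) == pytest.approx(0.25)
        assert max(scales) == pytest.approx(1.0)
        diam_um = {render_scene(s)[1].oocyte_diameter_um for s in specs}
        assert diam_um == {140.0}

    def test_disturbance_suite_has_clutter(self):
        specs = generate_suite("disturbance", 5, base_seed=4)
        assert all(5 <= s.clutter.count <= 20 for s in specs)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            generate_suite("focus", 5, 0)


@pytest.fixture(scope="module")
def small_suite():
    return generate_suite("background", 3, base_seed=8)


class TestRunBenchmark:

    def test_oracle_detector_scores_perfectly(self, small_suite):
        def oracle(img, truth, cfg):
            def as_detection(center, axes):
                return Detection(
                    found=True, center_px=center,
                    ellipse=EllipseParams(row=center[0], col=center[1], a=axes[0], b=axes[1], score=1.0),
                    diameter_px=2 * np.sqrt(axes[0] * axes[1]), confidence=1.0,
                )
            oo = as_detection(truth.oocyte_center_px, truth.oocyte_axes_px)
            pb = as_detection(truth.pb_center_px, truth.pb_axes_px)
            return build_report(oo, pb, truth.image_size, Calibration(truth.um_per_px))

        res = run_benchmark(small_suite, detector=oracle)
        assert res.aggregate["both_detection_rate_pct"] == 100.0
        assert res.aggregate["oocyte_diam_err_pct_max"] == pytest.approx(0.0, abs=1e-9)
        assert res.aggregate["pb_center_err_um_max"] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_across_reruns(self, small_suite):
        r1 = run_benchmark(small_suite)
        r2 = run_benchmark(small_suite)
        drop = ["runtime_s"]
        pd.testing.assert_frame_equal(
            r1.scenes.drop(columns=drop), r2.scenes.drop(columns=drop)
        )
        a1 = {k: v for k, v in r1.aggregate.items() if k != "runtime_s_mean"}
        a2 = {k: v for k, v in r2.aggregate.items() if k != "runtime_s_mean"}
        assert a1 == a2

    def test_failing_detector_recorded_not_raised(self, small_suite):
        def broken(img, truth, cfg):
            raise RuntimeError("boom")

        res = run_benchmark(small_suite, detector=broken)
        assert len(res.scenes) == 3
        assert res.aggregate["both_detection_rate_pct"] == 0.0

    def test_empty_suite_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_benchmark([])
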