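"""Gradient-weighted circular Hough voting and peak extraction, checked
against an independent exhaustive three-parameter Hough oracle."""

import numpy as np
import pytest
from scipy import ndimage

from oovision.gradients import EdgePointSet, auto_threshold, compute_gradients, threshold_edges
from oovision.hough import (
    HoughAccumulator,
    RadiusRange,
    find_center,
    find_center_excluding,
    vote_circular,
)
from oovision.imaging import FilterMask, GrayImage
from conftest import brute_hough_center, draw_disc


def _disc_edges(shape, center, radius, fg=200.0, bg=50.0, keep=0.10):
    field = compute_gradients(GrayImage(pixels=draw_disc(shape, center, radius, fg, bg)))
    return threshold_edges(field, auto_threshold(field, keep))


def _single_point(row, col, magnitude, orientation):
    return EdgePointSet(
        rows=np.array([row]),
        cols=np.array([col]),
        magnitudes=np.array([magnitude], dtype=float),
        orientations=np.array([orientation], dtype=float),
        threshold_used=0.0,
    )


class TestRadiusRange:
    def test_default_discretisation_is_one_px(self):
        rr = RadiusRange(35, 45)
        assert rr.n_steps == 11
        assert np.allclose(rr.radii, np.arange(35, 46))

    @pytest.mark.parametrize("rmin,rmax", [(0, 5), (-1, 5), (6, 5)])
    def test_invalid_ranges_rejected(self, rmin, rmax):
        with pytest.raises(ValueError):
            RadiusRange(rmin, rmax)


class TestVoteCircular:
    def test_single_point_votes_both_polarities(self):
        edges = _single_point(20, 20, magnitude=7.0, orientation=0.0)
        acc = vote_circular(edges, RadiusRange(5, 5, n_steps=1), (41, 41))
        nz = np.argwhere(acc.votes > 0)
        assert {tuple(p) for p in nz} == {(20, 15), (20, 25)}
        assert np.allclose(acc.votes[20, 15], 7.0)
        assert np.allclose(acc.votes[20, 25], 7.0)
        assert acc.total_weight == pytest.approx(14.0)

    def test_out_of_image_votes_discarded(self):
        edges = _single_point(2, 2, magnitude=1.0, orientation=np.pi)  # votes at x=-3 and x=7
        acc = vote_circular(edges, RadiusRange(5, 5, n_steps=1), (10, 10))
        assert acc.n_votes == 1
        assert acc.votes[2, 7] == 1.0

    def test_empty_edge_set_warns(self):
        empty = EdgePointSet(
            rows=np.array([], int), cols=np.array([], int),
            magnitudes=np.array([]), orientations=np.array([]), threshold_used=0.0,
        )
        with pytest.warns(UserWarning, match="empty"):
            acc = vote_circular(empty, RadiusRange(3, 5), (9, 9))
        assert acc.total_weight == 0
        assert find_center(acc) is None

    def test_weight_scaling_scales_cells_not_argmax(self):
        edges = _disc_edges((64, 64), (32.0, 30.0), 14.0)
        rr = RadiusRange(10, 18)
        acc1 = vote_circular(edges, rr, (64, 64))
        scaled = EdgePointSet(
            rows=edges.rows, cols=edges.cols,
            magnitudes=3.5 * edges.magnitudes,
            orientations=edges.orientations, threshold_used=edges.threshold_used,
        )
        acc2 = vote_circular(scaled, rr, (64, 64))
        assert np.allclose(acc2.votes, 3.5 * acc1.votes)
        c1, c2 = find_center(acc1), find_center(acc2)
        assert c1.row == pytest.approx(c2.row, abs=1e-9)
        assert c1.col == pytest.approx(c2.col, abs=1e-9)

    def test_circle_center_matches_brute_force_oracle(self):
        shape, center, radius = (64, 64), (31.0, 33.0), 20.0
        edges = _disc_edges(shape, center, radius)
        rr = RadiusRange(15, 25)
        acc = vote_circular(edges, rr, shape)
        est = find_center(acc)
        oracle = brute_hough_center(edges.rows, edges.cols, shape, np.arange(15, 26))
        assert np.hypot(est.row - oracle[0], est.col - oracle[1]) <= 1.0
        assert np.hypot(est.row - center[0], est.col - center[1]) <= 1.0

    def test_sharp_circle_outvotes_blurred_twin(self):
        shape = (80, 160)
        sharp = draw_disc(shape, (40.0, 40.0), 18.0)
        blurred = ndimage.gaussian_filter(draw_disc(shape, (40.0, 120.0), 18.0), 3.0)
        px = np.where(np.arange(160) < 80, sharp, blurred)
        field = compute_gradients(GrayImage(pixels=px))
        edges = threshold_edges(field, 1e-6)
        acc = vote_circular(edges, RadiusRange(15, 21), shape)
        sharp_peak = acc.votes[38:43, 38:43].sum()
        blurred_peak = acc.votes[38:43, 118:123].sum()
        assert sharp_peak > blurred_peak

    def test_translation_equivariance(self):
        shape = (72, 72)
        rr = RadiusRange(12, 18)
        e1 = _disc_edges(shape, (30.0, 30.0), 15.0)
        e2 = _disc_edges(shape, (36.0, 41.0), 15.0)  # shifted by (6, 11)
        c1 = find_center(vote_circular(e1, rr, shape))
        c2 = find_center(vote_circular(e2, rr, shape))
        assert c2.row - c1.row == pytest.approx(6.0, abs=1e-9)
        assert c2.col - c1.col == pytest.approx(11.0, abs=1e-9)

    def test_center_error_independent_of_contrast_polarity(self):
        shape, center, radius = (64, 64), (32.0, 32.0), 16.0
        rr = RadiusRange(12, 20)
        for fg, bg in ((220.0, 40.0), (40.0, 220.0)):
            edges = _disc_edges(shape, center, radius, fg=fg, bg=bg)
            est = find_center(vote_circular(edges, rr, shape))
            assert np.hypot(est.row - center[0], est.col - center[1]) <= 1.0


class TestFindCenter:
    def test_single_nonzero_cell(self):
        votes = np.zeros((20, 20))
        votes[7, 11] = 5.0
        est = find_center(HoughAccumulator(votes=votes, radius_range=RadiusRange(3, 5)))
        assert (est.row, est.col) == (7.0, 11.0)
        assert est.peak_vote > 0

    def test_tie_breaks_to_smallest_row_then_col(self):
        votes = np.zeros((30, 30))
        votes[10, 10] = 4.0
        votes[10, 20] = 4.0
        est = find_center(HoughAccumulator(votes=votes, radius_range=RadiusRange(2, 4)))
        assert (est.row, est.col) == (10.0, 10.0)

    def test_all_zero_accumulator_is_no_detection(self):
        acc = HoughAccumulator(votes=np.zeros((10, 10)), radius_range=RadiusRange(2, 4))
        assert find_center(acc) is None

    def test_matches_exhaustive_scan_of_smoothed_grid(self, rng):
        votes = rng.uniform(0, 1, size=(40, 40)) ** 8  # spiky surface
        acc = HoughAccumulator(votes=votes, radius_range=RadiusRange(3, 6))
        smoothed = ndimage.correlate(votes, FilterMask.binomial(3).coefficients, mode="nearest")
        r, c = np.unravel_index(np.argmax(smoothed), smoothed.shape)
        est = find_center(acc)
        assert np.hypot(est.row - r, est.col - c) <= 1.0


class TestFindCenterExcluding:
    def test_empty_mask_equals_find_center(self):
        votes = np.zeros((25, 25))
        votes[5, 5], votes[18, 3] = 9.0, 4.0
        acc = HoughAccumulator(votes=votes, radius_range=RadiusRange(2, 4))
        plain = find_center(acc)
        masked = find_center_excluding(acc, np.zeros((25, 25), bool))
        assert (plain.row, plain.col) == (masked.row, masked.col)
        assert plain.peak_vote == masked.peak_vote

    def test_masking_the_maximum_yields_second_peak(self):
        votes = np.zeros((40, 40))
        votes[10, 10] = 10.0
        votes[30, 30] = 8.0  # > 10/2, so it beats the masked peak's skirt
        acc = HoughAccumulator(votes=votes, radius_range=RadiusRange(2, 4))
        mask = np.zeros((40, 40), bool)
        mask[8:13, 8:13] = True
        est = find_center_excluding(acc, mask)
        assert (est.row, est.col) == (30.0, 30.0)

    def test_fully_masked_is_no_detection(self):
        votes = np.ones((10, 10))
        acc = HoughAccumulator(votes=votes, radius_range=RadiusRange(2, 3))
        assert find_center_excluding(acc, np.ones((10, 10), bool)) is None

    def test_mask_shape_mismatch_rejected(self):
        acc = HoughAccumulator(votes=np.ones((10, 10)), radius_range=RadiusRange(2, 3))
        with pytest.raises(ValueError):
            find_center_excluding(acc, np.zeros((5, 5), bool))
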