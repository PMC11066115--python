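import numpy as np
import pytest

from camangio import (
    PointAnnotation,
    RoiMask,
    SnakeParams,
    ValidationError,
    interpolate_boundary,
    interpolate_curve,
    skeletonize_mask,
    snake_segment,
)
from camangio.vessel_metrics import polyline_length

from conftest import make_disk_image, make_disk_mask, tube_mask


def contains_point(curve, point, atol=1e-9):
    return any(np.allclose(p, point, atol=atol) for p in curve)


class TestBoundaryInterpolation:
    def test_passes_through_square_corners(self):
        corners = [[10.0, 10.0], [10.0, 30.0], [30.0, 30.0], [30.0, 10.0]]
        b = interpolate_boundary(
            PointAnnotation(points=corners, closed=True), samples_per_segment=1
        )
        assert len(b.curve) >= 8
        for corner in corners:
            assert contains_point(b.curve, corner)
        assert b.area > 0

    def test_circle_recovered_within_half_pixel(self):
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.column_stack([64 + 20 * np.sin(theta), 64 + 20 * np.cos(theta)])
        b = interpolate_boundary(PointAnnotation(points=pts, closed=True), 16)
        radii = np.linalg.norm(b.curve - [64, 64], axis=1)
        assert np.abs(radii - 20).max() < 0.5

    def test_thin_triangle_is_valid(self):
        b = interpolate_boundary(
            PointAnnotation(points=[[5, 5], [5.4, 25], [6, 45]], closed=True), 4
        )
        assert b.area > 0

    def test_open_annotation_rejected(self):
        ann = PointAnnotation(points=[[0, 0], [1, 1], [2, 0]], closed=False)
        with pytest.raises(ValidationError):
            interpolate_boundary(ann)

    def test_duplicate_points_collapsed_with_warning(self):
        pts = [[0.0, 0.0], [0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]]
        with pytest.warns(UserWarning, match="duplicate"):
            b = interpolate_boundary(PointAnnotation(points=pts, closed=True), 2)
        assert b.area > 0

    def test_interpolant_hits_all_knots(self, rng):
        pts = rng.random((6, 2)) * 50 + 10
        b = interpolate_boundary(PointAnnotation(points=pts, closed=True), 8)
        for p in pts:
            assert contains_point(b.curve, p)


class TestCurveInterpolation:
    def test_two_points_give_straight_segment(self):
        curve = interpolate_curve(
            PointAnnotation(points=[[0.0, 0.0], [10.0, 5.0]], closed=False), 4
        )
        np.testing.assert_allclose(curve[:, 0] / 10.0, curve[:, 1] / 5.0, atol=1e-12)
        np.testing.assert_allclose(curve[0], [0, 0])
        np.testing.assert_allclose(curve[-1], [10, 5])

    def test_collinear_knots_stay_on_the_line(self):
        curve = interpolate_curve(
            PointAnnotation(points=[[0, 0], [5, 5], [10, 10]], closed=False), 8
        )
        assert np.abs(curve[:, 0] - curve[:, 1]).max() < 1e-9

    def test_sine_arc_within_half_pixel(self):
        x = np.linspace(0, 40, 5)
        pts = np.column_stack([50 + 10 * np.sin(x / 40 * np.pi), x])
        curve = interpolate_curve(PointAnnotation(points=pts, closed=False), 16)
        truth = 50 + 10 * np.sin(curve[:, 1] / 40 * np.pi)
        assert np.abs(curve[:, 0] - truth).max() < 0.5

    def test_closed_annotation_rejected(self):
        ann = PointAnnotation(points=[[0, 0], [1, 1], [2, 0]], closed=True)
        with pytest.raises(ValidationError):
            interpolate_curve(ann)


class TestSnake:
    def test_disk_phantom_boundary_recovery(self):
        img = make_disk_image((128, 128), (64, 64), 30)
        roi = RoiMask(mask=make_disk_mask((128, 128), (64, 64), 40), label="cam_vessel")
        b = snake_segment(img, roi)
        assert b.source == "snake"
        assert b.metadata["converged"]
        radii = np.linalg.norm(b.curve - [64, 64], axis=1)
        assert np.abs(radii - 30).mean() <= 1.5
        assert abs(b.area - np.pi * 900) / (np.pi * 900) <= 0.10

    @pytest.mark.parametrize("radius,contrast", [(10, 0.5), (20, 0.5), (30, 1.0)])
    def test_area_recovery_across_disk_sizes(self, radius, contrast):
        img = make_disk_image((128, 128), (64, 64), radius, contrast)
        roi = RoiMask(mask=make_disk_mask((128, 128), (64, 64), radius + 8))
        b = snake_segment(img, roi)
        true_area = np.pi * radius ** 2
        assert abs(b.area - true_area) / true_area <= 0.10

    def test_contour_on_boundary_barely_moves(self):
        img = make_disk_image((128, 128), (64, 64), 30)
        roi = RoiMask(mask=make_disk_mask((128, 128), (64, 64), 30))
        b = snake_segment(img, roi)
        radii = np.linalg.norm(b.curve - [64, 64], axis=1)
        assert np.abs(radii - 30).mean() < 1.0

    def test_uniform_image_shrinks_and_reports_convergence_flag(self):
        roi = RoiMask(mask=make_disk_mask((96, 96), (48, 48), 30))
        b = snake_segment(np.full((96, 96), 0.5), roi, SnakeParams(max_iter=200))
        radii = np.linalg.norm(b.curve - [48, 48], axis=1)
        assert radii.mean() < 30  # internal energy contracts the contour
        assert "converged" in b.metadata

    def test_shape_mismatch_rejected(self):
        roi = RoiMask(mask=make_disk_mask((64, 64), (32, 32), 10))
        with pytest.raises(ValidationError):
            snake_segment(np.zeros((32, 32)), roi)


class TestSkeletonize:
    def test_horizontal_bar_midline(self):
        mask = np.zeros((40, 80), dtype=bool)
        mask[20:23, 10:60] = True
        cl = skeletonize_mask(RoiMask(mask=mask), prune_px=5)
        assert cl.source == "skeleton"
        assert len(cl.curves) == 1
        assert polyline_length(cl.curves[0]) == pytest.approx(49, abs=2)
        assert np.all(np.abs(cl.curves[0][:, 0] - 21) <= 1)  # stays on the midline

    def test_single_pixel_yields_no_curve(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        cl = skeletonize_mask(RoiMask(mask=mask))
        assert cl.curves == []

    def test_plus_sign_decomposes_into_four_arms(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[28:31, 10:50] = True
        mask[10:50, 28:31] = True
        cl = skeletonize_mask(RoiMask(mask=mask), prune_px=5)
        assert len(cl.curves) == 4
        assert len(cl.junctions) == 1
        assert np.allclose(cl.junctions[0], (29, 29), atol=1.5)

    def test_skeleton_is_subset_of_mask(self):
        mask = tube_mask((100, 100), (20, 20), (80, 70), 4)
        cl = skeletonize_mask(RoiMask(mask=mask), prune_px=5)
        for curve in cl.curves:
            for r, c in np.round(curve).astype(int):
                assert mask[r, c]

    def test_consecutive_points_within_sqrt2(self):
        mask = tube_mask((100, 100), (20, 20), (80, 70), 4)
        cl = skeletonize_mask(RoiMask(mask=mask), prune_px=5)
        for curve in cl.curves:
            steps = np.linalg.norm(np.diff(curve, axis=0), axis=1)
            assert np.all(steps <= np.sqrt(2) + 1e-9)

    @pytest.mark.parametrize("angle_deg", [0, 30, 60])
    def test_tube_length_bound(self, angle_deg):
        """Skeleton length of a tube differs from the centerline length by
        at most the tube width plus twice the pruning allowance."""
        theta = np.deg2rad(angle_deg)
        length, w, prune = 120.0, 4.0, 5
        center = np.array([100.0, 100.0])
        d = np.array([np.sin(theta), np.cos(theta)])
        mask = tube_mask((200, 200), center - d * length / 2, center + d * length / 2, w)
        cl = skeletonize_mask(RoiMask(mask=mask), prune_px=prune)
        total = sum(polyline_length(c) for c in cl.curves)
        assert abs(total - length) <= w + 2 * prune

    def test_spur_pruning(self):
        mask = np.zeros((40, 80), dtype=bool)
        mask[20:23, 10:60] = True
        mask[16:20, 30] = True  # 4-px spur off the bar
        pruned = skeletonize_mask(RoiMask(mask=mask), prune_px=5)
        unpruned = skeletonize_mask(RoiMask(mask=mask), prune_px=0)
        assert len(pruned.curves) == 1
        assert len(unpruned.curves) >= 3  # spur splits the bar at a junction
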