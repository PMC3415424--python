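import math

import numpy as np
import pytest

from twodsil import (
    ArcSpec,
    BoundaryElement,
    ShapeSpec,
    contour_centroid,
    render_arc,
    render_bar,
    render_closed_shape,
)
from twodsil.stimuli import StimulusImage


def principal_axis_angle(img):
    """Independent image-moments oracle for the orientation of a bar."""
    pts = img.foreground()
    x = pts[:, 0] - pts[:, 0].mean()
    y = pts[:, 1] - pts[:, 1].mean()
    mxx, myy, mxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    return 0.5 * math.atan2(2 * mxy, mxx - myy)


class TestBar:
    def test_vertical_bar_extent(self):
        img = render_bar(40, math.pi / 2)
        pts = img.foreground()
        extent = pts[:, 1].max() - pts[:, 1].min() + 1
        assert abs(extent - 40) <= 1
        assert pts[:, 0].std() < 1.0

    def test_single_pixel_bar(self):
        img = render_bar(1, 0.3)
        assert 1 <= len(img.foreground()) <= 4

    @pytest.mark.parametrize("angle_deg", [0, 15, 30, 60, 90, 120, 165])
    def test_orientation_matches_moments_oracle(self, angle_deg):
        theta = math.radians(angle_deg)
        img = render_bar(120, theta)
        measured = principal_axis_angle(img) % math.pi
        diff = min(abs(measured - theta % math.pi),
                   math.pi - abs(measured - theta % math.pi))
        assert math.degrees(diff) < 2.0

    def test_overflow_raises(self):
        with pytest.raises(ValueError, match="canvas"):
            render_bar(500, 0.0)

    def test_binary_foreground(self):
        img = render_bar(50, 1.0)
        vals = np.unique(img.pixels)
        assert set(vals) <= {0.0, 1.0}


class TestArc:
    def test_full_circle_centroid(self):
        img = render_arc(ArcSpec(radius=150, arc_center=(199.5, 199.5)))
        cx, cy = contour_centroid(img)
        assert abs(cx - 199.5) <= 1 and abs(cy - 199.5) <= 1

    @pytest.mark.parametrize("radius", [20, 75, 150])
    def test_circle_fit_oracle(self, radius):
        # independent least-squares circle fit (Kasa method)
        img = render_arc(ArcSpec(radius=radius, arc_center=(199.5, 199.5),
                                 angular_extent=1.5 * math.pi))
        pts = img.foreground()
        x, y = pts[:, 0], pts[:, 1]
        A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        b = x * x + y * y
        cx, cy, c = np.linalg.lstsq(A, b, rcond=None)[0]
        r_fit = math.sqrt(c + cx * cx + cy * cy)
        assert abs(r_fit - radius) <= 1.0

    def test_two_half_arcs_equal_full_circle(self):
        kw = dict(radius=80, arc_center=(199.5, 199.5))
        full = render_arc(ArcSpec(angular_extent=2 * math.pi, orientation=0.0, **kw))
        h1 = render_arc(ArcSpec(angular_extent=math.pi, orientation=0.0, **kw))
        h2 = render_arc(ArcSpec(angular_extent=math.pi, orientation=math.pi, **kw))
        union = np.maximum(h1.pixels, h2.pixels)
        assert np.array_equal(union > 0, full.pixels > 0)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            ArcSpec(radius=-3)

    def test_arc_outside_canvas_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            render_arc(ArcSpec(radius=300, arc_center=(199.5, 199.5)))


def four_lobe_spec(rotation=0.0):
    return ShapeSpec(
        tuple(
            BoundaryElement("medium_convex", k * math.pi / 2, 40.0)
            for k in range(4)
        ),
        rotation=rotation,
    )


class TestClosedShape:
    def test_four_convex_lobes_roughly_circular(self):
        img = render_closed_shape(four_lobe_spec())
        pts = img.foreground()
        cx, cy = contour_centroid(img)
        r = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        assert r.std() / r.mean() < 0.1

    def test_rotation_by_two_pi_is_identity(self):
        a = render_closed_shape(four_lobe_spec(0.0))
        b = render_closed_shape(four_lobe_spec(2 * math.pi))
        assert np.array_equal(a.pixels, b.pixels)

    def test_sharp_angle_is_unique_turning_maximum(self):
        # discrete contour-curvature oracle: trace the contour as a polygon
        # ordered by angle about the centroid and find turning-angle peaks
        spec = ShapeSpec(
            (
                BoundaryElement("sharp_convex_angle", math.pi / 2, 55.0),
                BoundaryElement("medium_convex", math.pi, 30.0),
                BoundaryElement("medium_convex", 0.0, 30.0),
            )
        )
        img = render_closed_shape(spec)
        pts = img.foreground()
        cx, cy = contour_centroid(img)
        ang = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
        order = np.argsort(ang)
        poly = pts[order][::25]  # subsample to suppress pixel jitter
        nxt = np.roll(poly, -1, axis=0)
        prv = np.roll(poly, 1, axis=0)
        v1 = poly - prv
        v2 = nxt - poly
        turn = np.abs(np.arctan2(
            v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0],
            (v1 * v2).sum(axis=1),
        ))
        peak = turn.argmax()
        peak_angle = math.atan2(poly[peak, 1] - cy, poly[peak, 0] - cx)
        # the unique strong-turning locus sits at the sharp element's position
        assert abs(peak_angle - math.pi / 2) < 0.35
        strong = turn > 0.6 * turn.max()
        strong_angles = np.arctan2(poly[strong, 1] - cy, poly[strong, 0] - cx)
        assert np.ptp(strong_angles) < 0.7  # one locus, not several

    def test_unknown_element_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            BoundaryElement("wiggly", 0.0)

    def test_collapsing_concavity_rejected(self):
        spec = ShapeSpec(
            tuple(
                BoundaryElement("high_concave", k * math.pi / 3, 170.0)
                for k in range(6)
            )
        )
        with pytest.raises(ValueError, match="contour"):
            render_closed_shape(spec)

    def test_rotation_must_be_multiple_of_quarter_pi(self):
        with pytest.raises(ValueError, match="pi/4"):
            ShapeSpec((BoundaryElement("medium_convex", 0.0),), rotation=0.3)


class TestCentroid:
    def test_single_pixel(self):
        grid = np.zeros((50, 50))
        grid[20, 10] = 1.0
        assert contour_centroid(StimulusImage(grid)) == (10.0, 20.0)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError, match="empty"):
            contour_centroid(StimulusImage(np.zeros((10, 10))))

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(7)
        grid = np.zeros((60, 80))
        xs = rng.integers(0, 80, 40)
        ys = rng.integers(0, 60, 40)
        grid[ys, xs] = 1.0
        cx, cy = contour_centroid(StimulusImage(grid))
        pts = {(x, y) for x, y in zip(xs, ys)}
        ex = sum(p[0] for p in pts) / len(pts)
        ey = sum(p[1] for p in pts) / len(pts)
        assert abs(cx - ex) < 1e-9 and abs(cy - ey) < 1e-9


class TestProperties:
    def test_rendering_is_deterministic(self):
        a = render_arc(ArcSpec(radius=77), antialias=True)
        b = render_arc(ArcSpec(radius=77), antialias=True)
        assert np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_rotating_spec_rotates_centroid(self, k):
        spec = ShapeSpec(
            (
                BoundaryElement("high_convex", 0.3, 55.0),
                BoundaryElement("medium_concave", 2.2, 30.0),
                BoundaryElement("medium_convex", 4.0, 45.0),
            )
        )
        theta = k * math.pi / 4
        # coverage-weighted rendering: the centroid then tracks arc length
        # instead of raster density, which varies with tangent direction
        base = render_closed_shape(spec, antialias=True)
        rot = render_closed_shape(ShapeSpec(spec.elements, rotation=theta), antialias=True)
        c = 199.5
        bx, by = contour_centroid(base)
        rx, ry = contour_centroid(rot)
        ex = c + (bx - c) * math.cos(theta) - (by - c) * math.sin(theta)
        ey = c + (bx - c) * math.sin(theta) + (by - c) * math.cos(theta)
        assert math.hypot(rx - ex, ry - ey) < 1.5
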