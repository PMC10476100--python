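import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import berryripe as br
from berryripe import geometry
from berryripe.errors import (
    CoincidentPoints,
    DegenerateShape,
    EmptyMask,
    EmptyRegion,
    NoOppositePoint,
    TooSmall,
)
from berryripe.geometry import Chord, Line, Point

from oracles import brute_force_chord, loop_centroid, projection_point_line_distance


class TestPreprocess:
    def test_single_blob_unchanged(self, disk_mask):
        out = geometry.preprocess_mask(disk_mask)
        assert (out == disk_mask).all()

    def test_keeps_largest_component_only(self, disk_mask):
        m = disk_mask.copy()
        m[0, 0:3] = True  # 3-px speck
        out = geometry.preprocess_mask(m)
        assert (out == disk_mask).all()

    def test_fills_interior_hole(self, disk_mask):
        m = disk_mask.copy()
        m[30, 30] = False
        out = geometry.preprocess_mask(m)
        assert out[30, 30]
        assert out.sum() == disk_mask.sum()

    def test_empty_and_tiny_masks_rejected(self):
        with pytest.raises(EmptyMask):
            geometry.preprocess_mask(np.zeros((10, 10), dtype=bool))
        tiny = np.zeros((10, 10), dtype=bool)
        tiny[2:5, 2:5] = True  # 9 px < 64
        with pytest.raises(TooSmall):
            geometry.preprocess_mask(tiny)


class TestCentroid:
    def test_single_pixel(self):
        m = np.zeros((8, 8), dtype=bool)
        m[5, 3] = True
        c = geometry.compute_centroid(m)
        assert (c.x, c.y) == (3, 5)

    def test_filled_square_symmetry(self):
        m = np.zeros((6, 6), dtype=bool)
        m[0:4, 0:4] = True
        c = geometry.compute_centroid(m)
        assert (c.x, c.y) == (1.5, 1.5)

    def test_matches_loop_oracle_on_random_blob(self):
        rng = np.random.default_rng(11)
        m = np.zeros((30, 30), dtype=bool)
        ys, xs = rng.integers(0, 30, 200), rng.integers(0, 30, 200)
        m[ys, xs] = True
        c = geometry.compute_centroid(m)
        ox, oy = loop_centroid(m)
        assert c.x == pytest.approx(ox, abs=1e-12)
        assert c.y == pytest.approx(oy, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(EmptyMask):
            geometry.compute_centroid(np.zeros((4, 4), dtype=bool))


class TestContour:
    def test_thin_bar_all_pixels_on_contour(self):
        m = np.zeros((3, 7), dtype=bool)
        m[1, 1:6] = True
        pts = {tuple(p) for p in geometry.trace_contour(m)}
        assert pts == {(float(x), 1.0) for x in range(1, 6)}

    def test_filled_square_perimeter_count(self, square_mask):
        pts = geometry.trace_contour(square_mask)
        assert len({tuple(p) for p in pts}) == 4 * 10 - 4

    def test_contour_points_touch_background(self, disk_mask):
        pts = geometry.trace_contour(disk_mask)
        padded = np.pad(disk_mask, 1)
        for x, y in pts:
            xi, yi = int(x) + 1, int(y) + 1
            neighbors = [
                padded[yi - 1, xi], padded[yi + 1, xi],
                padded[yi, xi - 1], padded[yi, xi + 1],
            ]
            assert not all(neighbors)

    def test_closed_8_connected_loop(self, teardrop_mask):
        pts = geometry.trace_contour(teardrop_mask)
        loop = np.vstack([pts, pts[:1]])
        steps = np.abs(np.diff(loop, axis=0)).max(axis=1)
        assert (steps <= 1).all()
        fg = {tuple(p) for p in np.argwhere(teardrop_mask)[:, ::-1].astype(float)}
        assert {tuple(p) for p in pts} <= fg

    def test_two_pixels_degenerate(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1, 1:3] = True
        with pytest.raises(DegenerateShape):
            geometry.trace_contour(m)


class TestLines:
    def test_horizontal_pair_contains_both(self):
        line = geometry.line_through(Point(0, 0), Point(1, 0))
        assert geometry.point_line_distance(line, Point(0, 0)) == pytest.approx(0)
        assert geometry.point_line_distance(line, Point(1, 0)) == pytest.approx(0)

    def test_vertical_line_unit_offset(self):
        line = geometry.line_through(Point(0, 0), Point(0, 1))
        assert geometry.point_line_distance(line, Point(1, 0)) == pytest.approx(1.0)

    def test_axis_aligned_distance(self):
        # the line x = 0
        line = geometry.line_through(Point(0, -1), Point(0, 4))
        assert geometry.point_line_distance(line, Point(5, 7)) == pytest.approx(5.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(CoincidentPoints):
            geometry.line_through(Point(2, 3), Point(2, 3))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_residuals_and_projection_agreement(self, seed):
        rng = np.random.default_rng(seed)
        p, q, z = (Point(*rng.uniform(-50, 50, 2)) for _ in range(3))
        try:
            line = geometry.line_through(p, q)
        except CoincidentPoints:
            return
        assert abs(line.a * p.y + line.b * p.x + line.c) < 1e-9
        assert abs(line.a * q.y + line.b * q.x + line.c) < 1e-9
        expected = projection_point_line_distance((p.x, p.y), (q.x, q.y), (z.x, z.y))
        assert geometry.point_line_distance(line, z) == pytest.approx(expected, abs=1e-9)


class TestOppositeIntersection:
    def test_disk_antipodal(self, disk_mask):
        c = geometry.compute_centroid(disk_mask)
        contour = geometry.trace_contour(disk_mask)
        p0 = contour[0]
        opp = geometry.opposite_intersection(contour, c, 0)
        diameter = 2 * 25
        assert np.hypot(opp.x - p0[0], opp.y - p0[1]) == pytest.approx(
            diameter, abs=2.0
        )

    def test_rectangle_corner_maps_to_opposite_corner(self):
        m = np.zeros((30, 14), dtype=bool)
        m[2:26, 2:12] = True
        c = geometry.compute_centroid(m)
        contour = geometry.trace_contour(m)
        # index of the (2, 2) corner
        i = int(np.argwhere((contour == [2, 2]).all(axis=1))[0][0])
        opp = geometry.opposite_intersection(contour, c, i)
        assert (opp.x, opp.y) == (11, 25)

    def test_opposite_side_sign(self, teardrop_mask):
        c = geometry.compute_centroid(teardrop_mask)
        contour = geometry.trace_contour(teardrop_mask)
        carr = np.array([c.x, c.y])
        for i in range(0, len(contour), 7):
            p_i = contour[i] - carr
            try:
                opp = geometry.opposite_intersection(contour, c, i)
            except (NoOppositePoint, CoincidentPoints):
                continue
            p_o = np.array([opp.x, opp.y]) - carr
            u = p_i / np.linalg.norm(p_i)
            assert p_o @ u < 0


class TestLongestChord:
    def test_disk_chord_is_diameter(self, disk_mask):
        c = geometry.compute_centroid(disk_mask)
        contour = geometry.trace_contour(disk_mask)
        chord = geometry.find_longest_chord(contour, c)
        assert chord.length == pytest.approx(50.0, abs=2.0)

    def test_rectangle_chord_is_main_diagonal(self):
        m = np.zeros((70, 30), dtype=bool)
        m[2:62, 2:22] = True  # 20 x 60 rectangle
        c = geometry.compute_centroid(m)
        chord = geometry.find_longest_chord(geometry.trace_contour(m), c)
        diag = np.hypot(19, 59)
        assert chord.length == pytest.approx(diag, abs=2.0)

    def test_at_least_vertical_centroid_chord(self, teardrop_mask):
        c = geometry.compute_centroid(teardrop_mask)
        chord = geometry.find_longest_chord(geometry.trace_contour(teardrop_mask), c)
        col = teardrop_mask[:, int(round(c.x))]
        vertical_extent = np.ptp(np.nonzero(col)[0])
        assert chord.length >= vertical_extent - 1e-9

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = br.make_shape_mask(
                64, 56,
                rotation=float(rng.uniform(-90, 90)),
                seed=int(rng.integers(1 << 30)),
            )
            c = geometry.compute_centroid(m)
            contour = geometry.trace_contour(m)
            chord = geometry.find_longest_chord(contour, c)
            oracle = brute_force_chord(contour, c, eps=1.0)
            assert abs(chord.length - oracle) <= 1.0


class TestQuarterCuts:
    def test_vertical_chord_horizontal_cuts(self):
        chord = Chord(Point(0, 0), Point(0, 8), 8.0)
        (a, b, c), lines = geometry.quarter_cut_lines(chord)
        assert (a.x, a.y) == (0, 2) and (b.x, b.y) == (0, 4) and (c.x, c.y) == (0, 6)
        for line, p in zip(lines, (a, b, c)):
            # horizontal cut: same distance to any point of equal y
            assert geometry.point_line_distance(line, Point(99, p.y)) == pytest.approx(0)

    def test_diagonal_chord_perpendicular_cut(self):
        chord = Chord(Point(0, 0), Point(8, 8), float(np.hypot(8, 8)))
        (a, b, c), lines = geometry.quarter_cut_lines(chord)
        assert (b.x, b.y) == (4, 4)
        # l_b direction (1, -1): the point (5, 3) lies on it
        assert geometry.point_line_distance(lines[1], Point(5, 3)) == pytest.approx(0)

    def test_equal_quarters(self):
        chord = Chord(Point(1.5, -2.0), Point(10.0, 7.3), float(np.hypot(8.5, 9.3)))
        (a, b, c), _ = geometry.quarter_cut_lines(chord)
        pts = [chord.p_start, a, b, c, chord.p_end]
        gaps = [
            np.hypot(p2.x - p1.x, p2.y - p1.y) for p1, p2 in zip(pts, pts[1:])
        ]
        assert np.ptp(gaps) < 1e-9


class TestPartition:
    def test_vertical_rectangle_equal_bands(self):
        m = np.zeros((44, 12), dtype=bool)
        m[2:42, 2:10] = True  # 8 x 40
        chord = Chord(Point(5.5, 2), Point(5.5, 41), 40.0)
        part = geometry.partition_mask(m, chord)
        assert part.areas == [80, 80, 80, 80]
        # R1 is the bottom band
        assert part.regions[0][41, 5] and not part.regions[0][2, 5]

    def test_rotated_rectangle_near_equal_quarters(self):
        from skimage.transform import rotate

        m = np.zeros((80, 80), dtype=bool)
        m[20:60, 36:44] = True
        rot = rotate(m.astype(float), 30, order=0) > 0.5
        part = geometry.partition(rot)
        n = rot.sum()
        for area in part.areas:
            assert abs(area - n / 4) <= 0.05 * n

    def test_teardrop_tip_region_smallest(self, teardrop_mask):
        part = geometry.partition(teardrop_mask)
        assert part.areas[0] < part.areas[1]

    def test_completeness_disjointness_ordering(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            m = br.make_shape_mask(
                72, 64,
                rotation=float(rng.uniform(-45, 45)),
                seed=int(rng.integers(1 << 30)),
            )
            part = geometry.partition(m)
            union = np.zeros_like(m)
            overlap = np.zeros_like(m, dtype=int)
            for r in part.regions:
                union |= r
                overlap += r
            assert (union == m).all()
            assert overlap.max() == 1
            ys = [p.y for p in part.region_centroids]
            assert ys == sorted(ys, reverse=True)

    def test_rotation_equivariance_90deg(self, teardrop_mask):
        base = geometry.partition(teardrop_mask)
        rotated = geometry.partition(np.rot90(teardrop_mask))
        n = teardrop_mask.sum()
        assert sorted(base.areas) == pytest.approx(sorted(rotated.areas), abs=0.02 * n)

    def test_empty_region_raises(self):
        m = np.zeros((44, 12), dtype=bool)
        m[2:42, 2:10] = True
        # a chord far longer than the shape: upper bins get no pixels
        chord = Chord(Point(5.5, 2), Point(5.5, 200), 198.0)
        with pytest.raises(EmptyRegion):
            geometry.partition_mask(m, chord)

    def test_full_pipeline_records_geometry(self, teardrop_mask):
        part = geometry.partition(teardrop_mask)
        assert len(part.cut_intersections) == 3
        assert part.label_image().max() == 4
        lengths = [
            geometry.point_line_distance(line, p)
            for line, p in zip(part.cut_lines, part.quarter_points)
        ]
        assert max(lengths) < 1e-9
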