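"""Geometric partition of a fruit instance mask into four ordered sub-regions.

A strawberry reddens from the tip upward, so the informative axis of the
fruit is its long axis.  This module recovers that axis from a binary
instance mask alone: it computes the mask centroid, finds the longest chord
through the centroid with both endpoints on the outer contour, erects three
perpendicular cut lines at the quarter points of that chord, and splits the
mask into four sub-regions R1..R4 ordered bottom-to-top in image
coordinates (R1 contains the tip for a fruit hanging downward).

Coordinate convention: 0-based ``(x, y)`` = (column, row); rows increase
downward, so "bottom" means maximal ``y``.  Masks are 2-D boolean (or 0/1)
arrays indexed ``[row, column]``.

Lines use the implicit form ``A*y + B*x + C = 0`` normalized to
``A**2 + B**2 == 1``, so the point-line distance reduces to the absolute
residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    CoincidentPoints,
    DegenerateShape,
    EmptyMask,
    EmptyRegion,
    NoOppositePoint,
    TooSmall,
)

logger = logging.getLogger(__name__)

#: Masks smaller than this many foreground pixels are rejected: quartering
#: a tiny blob along its longest chord is not meaningful.
MIN_MASK_AREA = 64

#: Chord-length ties closer than this (pixels) are broken toward the
#: smallest contour start index, for determinism.
CHORD_TIE_TOL = 1e-6

#: Opposite-side contour points whose distance to a centroid-line is within
#: this much (pixels) of the minimum all count as intersections of the line
#: with the contour.  Discrete contours rarely contain exact intersections;
#: one pixel is the discretization scale of the contour itself.
INTERSECTION_TOL = 1.0


@dataclass(frozen=True)
class Point:
    """A 2-D point in pixel coordinates (x = column, y = row)."""

    x: float
    y: float

    def __iter__(self):
        return iter((self.x, self.y))


@dataclass(frozen=True)
class Line:
    """Implicit line ``a*y + b*x + c = 0`` with ``a**2 + b**2 == 1``."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class Chord:
    """A maximal centroid-chord of the mask, with contour endpoints."""

    p_start: Point
    p_end: Point
    length: float

    @property
    def direction(self) -> tuple[float, float]:
        """Unit vector from ``p_start`` to ``p_end``."""
        dx = self.p_end.x - self.p_start.x
        dy = self.p_end.y - self.p_start.y
        n = float(np.hypot(dx, dy))
        return dx / n, dy / n


@dataclass
class SubRegionPartition:
    """Four ordered sub-masks plus the geometry that produced them.

    ``regions[0]`` is R1, the sub-region whose centroid has the largest row
    coordinate (bottom-most in image coordinates), down to ``regions[3]``
    = R4 at the top.  Regions are pairwise disjoint and their union is the
    parent mask.
    """

    regions: list[np.ndarray]
    chord: Chord
    quarter_points: tuple[Point, Point, Point]
    cut_lines: tuple[Line, Line, Line]
    region_centroids: list[Point]
    cut_intersections: list[tuple[Point, Point]] = field(default_factory=list)

    def label_image(self) -> np.ndarray:
        """Render the partition as a label image (0 background, 1..4 = R1..R4)."""
        out = np.zeros(self.regions[0].shape, dtype=np.uint8)
        for k, region in enumerate(self.regions, start=1):
            out[region] = k
        return out

    @property
    def areas(self) -> list[int]:
        return [int(r.sum()) for r in self.regions]


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise EmptyMask(f"mask must be 2-D, got shape {arr.shape}")
    return arr > 0


def preprocess_mask(raw_mask: np.ndarray, min_area: int = MIN_MASK_AREA) -> np.ndarray:
    """Reduce a raw instance mask to its largest 8-connected component, holes filled.

    Occlusion can split an instance mask into fragments; only the largest
    fragment is kept (a warning is logged when others are discarded).

    Raises
    ------
    EmptyMask
        If the mask has no foreground pixels.
    TooSmall
        If the largest component is below ``min_area`` pixels.
    """
    mask = _as_bool_mask(raw_mask)
    if not mask.any():
        raise EmptyMask("mask has no foreground pixels")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        logger.warning(
            "mask has %d components; keeping largest (%d px), discarding %d px",
            n, counts[keep - 1], int(counts.sum() - counts[keep - 1]),
        )
        mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)
    area = int(mask.sum())
    if area < min_area:
        raise TooSmall(f"largest component has {area} px < minimum {min_area}")
    return mask


def compute_centroid(mask: np.ndarray) -> Point:
    """Center of mass of the foreground: the mean of foreground pixel coordinates."""
    mask = _as_bool_mask(mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise EmptyMask("cannot compute centroid of an empty mask")
    return Point(float(xs.mean()), float(ys.mean()))


# Moore neighborhood in clockwise order starting from west, as (dy, dx).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the ordered outer boundary of a single-component mask.

    Moore-neighbor tracing with Jacob's stopping criterion.  Returns an
    ``(M, 2)`` array of ``(x, y)`` pixel coordinates forming a closed
    8-connected loop; thin shapes are traversed out and back, so a pixel
    may appear more than once.

    Raises
    ------
    DegenerateShape
        If fewer than 3 boundary points exist.
    EmptyMask
        If the mask is empty.
    """
    mask = _as_bool_mask(mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise EmptyMask("cannot trace contour of an empty mask")
    # pad so neighborhood lookups never leave the array
    padded = np.pad(mask, 1)
    # start at the topmost-then-leftmost foreground pixel; its west neighbor
    # is guaranteed background, giving a valid initial backtrack direction
    start_idx = np.lexsort((xs, ys))[0]
    sy, sx = int(ys[start_idx]) + 1, int(xs[start_idx]) + 1

    # walk state: (row, col, backtrack) where backtrack indexes the Moore
    # direction of the background pixel the walk arrived from; the trace is
    # closed when the start state recurs
    start = (sy, sx, 0)
    contour: list[tuple[int, int]] = [(sx, sy)]
    seen: set[tuple[int, int, int]] = {start}
    state = start
    while True:
        cy, cx, back = state
        nxt = None
        for k in range(1, 9):
            d = (back + k) % 8
            dy, dx = _MOORE[d]
            ny, nx = cy + dy, cx + dx
            if padded[ny, nx]:
                # new backtrack: the (background) neighbor scanned just
                # before this one, seen from the new pixel
                prev = (back + k - 1) % 8
                py, px = cy + _MOORE[prev][0], cx + _MOORE[prev][1]
                nxt = (ny, nx, _MOORE.index((py - ny, px - nx)))
                break
        if nxt is None or nxt in seen:
            # isolated pixel, or loop closed (possibly without reproducing
            # the exact start backtrack)
            break
        seen.add(nxt)
        contour.append((nxt[1], nxt[0]))
        state = nxt

    if len({p for p in contour}) < 3:
        raise DegenerateShape("contour has fewer than 3 distinct points")
    return np.array(contour, dtype=float) - 1.0  # undo padding offset


def line_through(p: Point, q: Point) -> Line:
    """The line through two distinct points, in normalized implicit form."""
    dx, dy = q.x - p.x, q.y - p.y
    n = float(np.hypot(dx, dy))
    if n < 1e-12:
        raise CoincidentPoints(f"points coincide: {p} and {q}")
    a, b = dx / n, -dy / n
    c = -(a * p.y + b * p.x)
    return Line(a, b, c)


def point_line_distance(line: Line, p: Point) -> float:
    """Perpendicular distance (pixels) from a point to a line."""
    return abs(line.a * p.y + line.b * p.x + line.c) / float(
        np.hypot(line.a, line.b)
    )


def _opposite_candidates(
    points: np.ndarray, centroid: Point, i: int
) -> tuple[np.ndarray, np.ndarray]:
    """Signed projections and line distances of all contour points for index ``i``.

    The line runs through ``points[i]`` and the centroid.  Projections are
    onto the unit vector from the centroid toward ``points[i]``, so
    ``points[i]`` itself has a positive projection and opposite-side points
    have negative ones.
    """
    c = np.array([centroid.x, centroid.y])
    v = points[i] - c
    n = float(np.hypot(*v))
    if n < 1e-9:
        raise CoincidentPoints("contour point coincides with the centroid")
    u = v / n
    rel = points - c
    proj = rel @ u
    dist = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    return proj, dist


def opposite_intersection(
    contour: np.ndarray, centroid: Point, i: int
) -> Point:
    """The contour point closest to the line through ``contour[i]`` and the centroid,
    restricted to the far side of the centroid.

    This approximates the second intersection of the centroid-line with the
    contour: a zero minimum distance means the point lies exactly on the
    line.  The constructing point itself and all same-side points are
    excluded, so the result is always the *other* intersection.

    Raises
    ------
    NoOppositePoint
        If no contour point lies on the opposite side (pathological shape).
    """
    points = np.asarray(contour, dtype=float)
    proj, dist = _opposite_candidates(points, centroid, i)
    opposite = proj < 0
    if not opposite.any():
        raise NoOppositePoint(f"no contour point opposite index {i}")
    cand = np.nonzero(opposite)[0]
    j = cand[int(np.argmin(dist[cand]))]
    return Point(float(points[j, 0]), float(points[j, 1]))


def find_longest_chord(contour: np.ndarray, centroid: Point) -> Chord:
    """The longest line segment through the centroid with contour endpoints.

    Every contour point P_i defines a line through the centroid.  Its
    second intersection with the contour is approximated on the opposite
    side of the centroid: every opposite point whose line distance exceeds
    the minimum by less than ``INTERSECTION_TOL`` counts as an intersection
    (a discrete contour rarely contains the exact one, and near-ties are
    below the contour's own discretization), and the farthest such point
    is taken.  The candidate pair
    maximizing Euclidean length over all i is returned.  Ties within
    1e-6 px go to the smallest start index.
    """
    points = np.asarray(contour, dtype=float)
    m = len(points)
    if m < 3:
        raise DegenerateShape("need at least 3 contour points")
    best_len = -1.0
    best: tuple[int, np.ndarray] | None = None
    for i in range(m):
        try:
            proj, dist = _opposite_candidates(points, centroid, i)
        except CoincidentPoints:
            continue
        opposite = proj < 0
        if not opposite.any():
            continue
        cand = np.nonzero(opposite)[0]
        dmin = float(dist[cand].min())
        near = cand[dist[cand] <= dmin + INTERSECTION_TOL]
        lengths = np.hypot(*(points[near] - points[i]).T)
        k = int(np.argmax(lengths))
        length = float(lengths[k])
        j = near[k]
        if length > best_len + CHORD_TIE_TOL:
            best_len = length
            best = (i, points[j])
    if best is None:
        raise NoOppositePoint("no centroid-chord could be constructed")
    i, pj = best
    return Chord(
        p_start=Point(float(points[i, 0]), float(points[i, 1])),
        p_end=Point(float(pj[0]), float(pj[1])),
        length=best_len,
    )


def quarter_cut_lines(
    chord: Chord,
) -> tuple[tuple[Point, Point, Point], tuple[Line, Line, Line]]:
    """Quarter points a, b, c of the chord and the perpendicular cut lines through them."""
    ux, uy = chord.direction
    pts = []
    lines = []
    for t in (0.25, 0.5, 0.75):
        px = chord.p_start.x + t * (chord.p_end.x - chord.p_start.x)
        py = chord.p_start.y + t * (chord.p_end.y - chord.p_start.y)
        p = Point(px, py)
        # perpendicular to the chord: points satisfying u . (q - p) = 0,
        # i.e. uy*y + ux*x - (uy*py + ux*px) = 0, already normalized
        lines.append(Line(uy, ux, -(uy * py + ux * px)))
        pts.append(p)
    return (pts[0], pts[1], pts[2]), (lines[0], lines[1], lines[2])


def _cut_intersections(
    contour: np.ndarray, chord: Chord, quarter_points: tuple[Point, Point, Point]
) -> list[tuple[Point, Point]]:
    """For each cut line, the nearest contour point on each side of the chord."""
    points = np.asarray(contour, dtype=float)
    ux, uy = chord.direction
    out = []
    for qp in quarter_points:
        rel = points - np.array([qp.x, qp.y])
        along = rel @ np.array([ux, uy])          # distance to the cut line
        side = rel[:, 0] * uy - rel[:, 1] * ux     # which side of the chord
        pair = []
        for sel in (side >= 0, side < 0):
            idx = np.nonzero(sel)[0]
            if idx.size == 0:
                pair.append(qp)
                continue
            j = idx[int(np.argmin(np.abs(along[idx])))]
            pair.append(Point(float(points[j, 0]), float(points[j, 1])))
        out.append((pair[0], pair[1]))
    return out


def partition_mask(
    mask: np.ndarray, chord: Chord, contour: np.ndarray | None = None
) -> SubRegionPartition:
    """Split the mask into four sub-regions along the chord and order them bottom-up.

    Each foreground pixel is assigned by its signed projection onto the
    chord direction, binned at 1/4, 1/2 and 3/4 of the chord length
    (equivalent to cutting with the infinite perpendicular lines; identical
    to segment-based cutting for convex contours).  Bins are half-open
    ``[k*L/4, (k+1)*L/4)`` with the last bin closed; projections outside
    ``[0, L]`` clamp into the end bins.  Regions are then relabeled R1..R4
    by descending centroid row, so R1 is bottom-most.

    Raises
    ------
    EmptyRegion
        If any quartile bin receives zero pixels.
    """
    mask = _as_bool_mask(mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise EmptyMask("cannot partition an empty mask")
    ux, uy = chord.direction
    t = (xs - chord.p_start.x) * ux + (ys - chord.p_start.y) * uy
    bins = np.clip(np.floor(t / (chord.length / 4.0)).astype(int), 0, 3)

    chord_order_regions = []
    for k in range(4):
        sub = np.zeros_like(mask)
        sel = bins == k
        if not sel.any():
            raise EmptyRegion(f"quartile bin {k} received zero pixels")
        sub[ys[sel], xs[sel]] = True
        chord_order_regions.append(sub)

    centroids = [compute_centroid(r) for r in chord_order_regions]
    # sort bottom (max row) to top; stable so chord order breaks exact ties
    order = sorted(range(4), key=lambda k: -centroids[k].y)
    regions = [chord_order_regions[k] for k in order]
    region_centroids = [centroids[k] for k in order]

    quarter_points, cut_lines = quarter_cut_lines(chord)
    intersections = (
        _cut_intersections(contour, chord, quarter_points)
        if contour is not None
        else []
    )
    return SubRegionPartition(
        regions=regions,
        chord=chord,
        quarter_points=quarter_points,
        cut_lines=cut_lines,
        region_centroids=region_centroids,
        cut_intersections=intersections,
    )


def partition(raw_mask: np.ndarray, min_area: int = MIN_MASK_AREA) -> SubRegionPartition:
    """Full geometric pipeline: preprocess, centroid, contour, chord, partition."""
    mask = preprocess_mask(raw_mask, min_area=min_area)
    centroid = compute_centroid(mask)
    contour = trace_contour(mask)
    chord = find_longest_chord(contour, centroid)
    return partition_mask(mask, chord, contour=contour)
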