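"""Planar geometry primitives for contour morphometry.

All polygons are (n, 2) float arrays of (x, y) = (column, row) vertices in
pixel-centre coordinates, implicitly closed (last vertex connects back to
the first).  Counter-clockwise orientation is defined as positive shoelace
area under the usual formula, which on screen coordinates (y growing
downward) corresponds to clockwise traversal on screen — every routine
here only relies on the sign convention, never on screen handedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "polygon_signed_area",
    "polygon_area",
    "polygon_perimeter",
    "convex_hull",
    "hull_area",
    "hull_perimeter",
    "approx_contour",
    "ConvexityDefect",
    "convexity_defects",
    "defect_sum",
    "defect_max",
    "point_segment_distance",
    "min_area_rect_sides",
]


def _as_poly(poly) -> np.ndarray:
    p = np.asarray(poly, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"polygon must be an (n, 2) array, got shape {p.shape}")
    return p


def polygon_signed_area(poly) -> float:
    """Signed shoelace area ½·Σ(x_i·y_{i+1} − x_{i+1}·y_i).

    Positive for counter-clockwise orientation.  This is the discrete
    evaluation of the Green's-theorem line integral ∮ x dy around the
    closed contour.
    """
    p = _as_poly(poly)
    if len(p) < 3:
        raise ValueError(f"polygon needs >= 3 vertices, got {len(p)}")
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(poly) -> float:
    """Absolute enclosed area (px²) via the shoelace formula."""
    return abs(polygon_signed_area(poly))


def polygon_perimeter(poly, closed: bool = True) -> float:
    """Total edge length of a polygon or polyline (px)."""
    p = _as_poly(poly)
    if len(p) < 2:
        return 0.0
    diffs = np.diff(p, axis=0)
    length = float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))
    if closed:
        length += float(np.hypot(*(p[0] - p[-1])))
    return length


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> np.ndarray:
    """Convex hull by Andrew's monotone chain, CCW, collinear vertices
    dropped.

    Raises if all points are collinear (the hull would be degenerate).
    """
    pts = _as_poly(points)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        raise ValueError("convex hull needs >= 3 distinct points")
    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    sorted_pts = uniq[order]

    def half(points_iter):
        chain: list[np.ndarray] = []
        for pt in points_iter:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], pt) <= 0:
                chain.pop()
            chain.append(pt)
        return chain

    lower = half(sorted_pts)
    upper = half(sorted_pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise ValueError("all points are collinear; hull is degenerate")
    return hull


def hull_area(hull) -> float:
    """Enclosed area of a convex hull polygon (px²)."""
    return polygon_area(hull)


def hull_perimeter(hull) -> float:
    """Boundary length of a convex hull polygon (px)."""
    return polygon_perimeter(hull)


def point_segment_distance(point, seg_start, seg_end) -> float:
    """Euclidean distance from a point to a line segment."""
    p = np.asarray(point, dtype=float)
    a = np.asarray(seg_start, dtype=float)
    b = np.asarray(seg_end, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(p - a)))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.hypot(*(p - proj)))


def _dp_open(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Iterative Douglas–Peucker on an open polyline (keeps endpoints)."""
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        seg = points[lo + 1 : hi]
        a, b = points[lo], points[hi]
        ab = b - a
        norm = np.hypot(*ab)
        if norm == 0.0:
            dists = np.hypot(seg[:, 0] - a[0], seg[:, 1] - a[1])
        else:
            dists = np.abs((seg[:, 0] - a[0]) * ab[1] - (seg[:, 1] - a[1]) * ab[0]) / norm
        idx = int(np.argmax(dists))
        if dists[idx] > epsilon:
            split = lo + 1 + idx
            keep[split] = True
            stack.append((lo, split))
            stack.append((split, hi))
    return points[keep]


def approx_contour(poly, epsilon: float | None = None) -> np.ndarray:
    """Douglas–Peucker simplification of a closed contour.

    ``epsilon`` defaults to 1% of the contour perimeter.  ``epsilon = 0``
    returns the input unchanged.  The closed polygon is split at two
    mutually distant anchor vertices, each open chain is simplified, and a
    final sweep drops any vertex lying within ``epsilon`` of the segment
    joining its neighbours (so anchors that landed on a straight stretch
    do not survive by accident).
    """
    p = _as_poly(poly)
    if len(p) < 3:
        raise ValueError("contour needs >= 3 vertices")
    if epsilon is None:
        epsilon = 0.01 * polygon_perimeter(p)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return p.copy()
    # anchor at vertex 0 and the vertex farthest from it
    d0 = np.hypot(p[:, 0] - p[0, 0], p[:, 1] - p[0, 1])
    far = int(np.argmax(d0))
    chain1 = _dp_open(p[: far + 1], epsilon)
    chain2 = _dp_open(np.vstack([p[far:], p[:1]]), epsilon)
    simplified = np.vstack([chain1[:-1], chain2[:-1]])
    # closing sweep: drop near-collinear survivors (anchors included)
    changed = True
    while changed and len(simplified) > 3:
        changed = False
        n = len(simplified)
        for i in range(n):
            if len(simplified) <= 3:
                break
            j = i % len(simplified)
            prev = simplified[j - 1]
            nxt = simplified[(j + 1) % len(simplified)]
            if point_segment_distance(simplified[j], prev, nxt) <= epsilon:
                simplified = np.delete(simplified, j, axis=0)
                changed = True
                break
    return simplified


@dataclass(frozen=True)
class ConvexityDefect:
    """One concave excursion of the contour below a hull edge.

    The hull edge is the line A·x + B·y + C = 0 through ``edge_start`` and
    ``edge_end``; ``farthest_point`` is the contour vertex between the two
    hull vertices that maximises the point-line distance ``depth``.
    """

    edge_start: tuple[float, float]
    edge_end: tuple[float, float]
    line: tuple[float, float, float]
    farthest_point: tuple[float, float]
    depth: float


def convexity_defects(contour, hull) -> list[ConvexityDefect]:
    """Find one defect per hull edge that subtends off-hull contour
    vertices.

    ``hull`` must consist of vertices of ``contour``.  For each pair of
    hull vertices consecutive along the contour, the intermediate contour
    vertices are scanned and the one farthest from the hull-edge line is
    recorded; edges with no intermediate vertex contribute no defect, so a
    convex contour yields an empty list.
    """
    c = _as_poly(contour)
    h = _as_poly(hull)
    # locate each hull vertex on the contour
    hull_idx = []
    for v in h:
        matches = np.nonzero(np.all(np.isclose(c, v, atol=1e-9), axis=1))[0]
        if len(matches) == 0:
            raise ValueError("hull vertex not found on contour: hull/contour mismatch")
        hull_idx.append(int(matches[0]))
    hull_idx = sorted(set(hull_idx))
    n = len(c)
    defects: list[ConvexityDefect] = []
    for k, i in enumerate(hull_idx):
        j = hull_idx[(k + 1) % len(hull_idx)]
        inter = (
            list(range(i + 1, j)) if j > i else list(range(i + 1, n)) + list(range(0, j))
        )
        if not inter:
            continue
        p1, p2 = c[i], c[j]
        A = p2[1] - p1[1]
        B = p1[0] - p2[0]
        C = p2[0] * p1[1] - p1[0] * p2[1]
        norm = np.hypot(A, B)
        if norm == 0.0:
            continue
        pts = c[inter]
        dists = np.abs(A * pts[:, 0] + B * pts[:, 1] + C) / norm
        best = int(np.argmax(dists))
        depth = float(dists[best])
        defects.append(
            ConvexityDefect(
                edge_start=(float(p1[0]), float(p1[1])),
                edge_end=(float(p2[0]), float(p2[1])),
                line=(float(A), float(B), float(C)),
                farthest_point=(float(pts[best][0]), float(pts[best][1])),
                depth=depth,
            )
        )
    return defects


def defect_sum(defects: list[ConvexityDefect]) -> float:
    """Σ_i depth_i over all convexity defects (px); 0 for a convex shape."""
    return float(sum(d.depth for d in defects))


def defect_max(defects: list[ConvexityDefect]) -> float:
    """max_i depth_i over all convexity defects (px); 0 for a convex shape."""
    return float(max((d.depth for d in defects), default=0.0))


def min_area_rect_sides(points) -> tuple[float, float]:
    """Side lengths (long, short) of the minimum-area enclosing rectangle.

    Diagnostic companion to the axis-aligned bounding box; computed with
    shapely's rotating-calipers implementation.
    """
    from shapely.geometry import MultiPoint

    rect = MultiPoint([tuple(p) for p in _as_poly(points)]).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:-1]
    if len(coords) < 4:  # degenerate (line/point)
        raise ValueError("min-area rectangle degenerate: collinear points")
    s1 = float(np.hypot(*(coords[1] - coords[0])))
    s2 = float(np.hypot(*(coords[2] - coords[1])))
    return (max(s1, s2), min(s1, s2))
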