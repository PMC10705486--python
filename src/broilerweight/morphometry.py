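"""The 25 morphometric features of a segmented bird.

From a binary instance mask and its depth-distance image the extractor
computes 16 two-dimensional shape descriptors (projected area by Green's
formula, contour and hull perimeters, Douglas–Peucker approximate
contour, convexity-defect statistics, bounding-box ratios, moment-based
ellipse axes, …), eight depth statistics in millimetres, and the
approximate back volume

    V = Area · max{D(x_p, y_p) over the contour} − Σ_p D(x_p, y_p),

the volume of the valley the animal's back carves into the flat ground
plane, with depths D in mm and the reference height taken at the mask
edge.  The head is deliberately left in the mask: removing it costs
information and the features are designed to tolerate it.

Contours are traced on pixel centres (Moore neighbourhood), so the
Green's-formula area of a blob undershoots its pixel count by roughly
half the perimeter; the volume formula therefore uses the non-missing
masked pixel count as its discrete area so that the Riemann sum is
unbiased (a flag restores the contour area for comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from skimage import measure

from . import geometry
from .depth_io import FEATURE_NAMES, DepthImage

__all__ = [
    "Contour",
    "MorphometricFeatures",
    "extract_contour",
    "fit_ellipse",
    "box_features",
    "depth_statistics",
    "approximate_volume",
    "extract_all_features",
]

# clockwise Moore neighbourhood starting West, (row, col) offsets
_MOORE = (
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 1), (1, 1), (1, 0), (1, -1),
)


@dataclass(frozen=True)
class Contour:
    """Closed boundary polygon of one instance, on pixel centres.

    Vertices are (x, y) = (column, row) coordinates ordered so the
    shoelace area is positive (the CCW convention shared with
    :mod:`broilerweight.geometry`); collinear runs are merged.
    """

    vertices: np.ndarray

    @property
    def perimeter(self) -> float:
        return geometry.polygon_perimeter(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)


_DIR_INDEX = {off: i for i, off in enumerate(_MOORE)}


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixels of a connected component.

    Moore-neighbour tracing: from the raster-first foreground pixel
    (whose West neighbour is guaranteed background), repeatedly scan the
    eight neighbours of the current pixel clockwise starting from the
    last background pixel visited; the first foreground hit becomes the
    next boundary pixel.  Terminates when the (pixel, backtrack) state
    returns to its initial value.  Returns an (n, 2) array of (row, col)
    positions; pixels may repeat where the component is one pixel wide.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # raster order: topmost then leftmost

    def fg(r: int, c: int) -> bool:
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])

    p = start
    bdir = 0  # backtrack direction index relative to p; West of start is background
    initial_state = (p, bdir)
    boundary = [start]
    seen = {initial_state}
    max_steps = 8 * int(mask.sum()) + 8
    for _ in range(max_steps):
        for k in range(1, 9):
            d = (bdir + k) % 8
            r, c = p[0] + _MOORE[d][0], p[1] + _MOORE[d][1]
            if fg(r, c):
                prev_d = (bdir + k - 1) % 8  # last background probe, from old p
                bpix = (p[0] + _MOORE[prev_d][0], p[1] + _MOORE[prev_d][1])
                p = (r, c)
                bdir = _DIR_INDEX[(bpix[0] - p[0], bpix[1] - p[1])]
                break
        else:  # isolated pixel: no foreground neighbour at all
            return np.array([start])
        state = (p, bdir)
        if state == initial_state:
            return np.array(boundary)
        if state in seen:  # safety net: close at the first repeated state
            return np.array(boundary)
        seen.add(state)
        boundary.append(p)
    return np.array(boundary)


def _merge_collinear(vertices: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop vertices lying on the straight line of their neighbours while
    the traversal keeps moving forward (spikes are preserved)."""
    out = list(map(tuple, vertices))
    changed = True
    while changed and len(out) > 3:
        changed = False
        n = len(out)
        keep = []
        for i in range(n):
            prev, cur, nxt = out[i - 1], out[i], out[(i + 1) % n]
            v1 = (cur[0] - prev[0], cur[1] - prev[1])
            v2 = (nxt[0] - cur[0], nxt[1] - cur[1])
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            dot = v1[0] * v2[0] + v1[1] * v2[1]
            if abs(cross) <= tol and dot > 0:
                changed = True
                continue
            keep.append(cur)
        out = keep if len(keep) >= 3 else out
        if len(keep) < 3:
            break
    return np.array(out, dtype=float)


def extract_contour(mask: np.ndarray) -> Contour:
    """Trace the outer boundary of the largest connected component.

    The mask must span at least 3 pixels in extent so that the boundary
    encloses a non-degenerate polygon.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot extract a contour from an empty mask")
    labels = measure.label(m, connectivity=2)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())[1:]
        m = labels == (int(np.argmax(counts)) + 1)
    rc = _trace_boundary(m)
    # (row, col) -> (x, y)
    poly = np.column_stack([rc[:, 1], rc[:, 0]]).astype(float)
    # drop consecutive duplicates (possible at spike turn-arounds)
    dedup = [poly[0]]
    for v in poly[1:]:
        if not np.array_equal(v, dedup[-1]):
            dedup.append(v)
    poly = np.array(dedup)
    if len(poly) < 3:
        raise ValueError(
            "mask too thin for a contour: needs >= 3 px extent in both directions"
        )
    signed = geometry.polygon_signed_area(poly)
    if abs(signed) < 0.5:
        raise ValueError(
            "mask too thin for a contour: boundary encloses no area"
        )
    if signed < 0:
        poly = poly[::-1]
    poly = _merge_collinear(poly)
    return Contour(vertices=poly)


def fit_ellipse(mask: np.ndarray) -> tuple[float, float, float]:
    """Moment-based ellipse fit of a mask.

    Axis lengths are 4·sqrt of the eigenvalues of the pixel-coordinate
    covariance (so a filled disc of radius r yields its diameter 2r), the
    same normalisation scikit-image's ``regionprops`` uses.  Returns
    (major_axis_length, minor_axis_length, eccentricity) with
    eccentricity = sqrt(1 − (minor/major)²).
    """
    m = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(m)
    if len(rows) < 5:
        raise ValueError(f"ellipse fit needs >= 5 pixels, got {len(rows)}")
    x = cols.astype(float)
    y = rows.astype(float)
    xc, yc = x.mean(), y.mean()
    cxx = np.mean((x - xc) ** 2)
    cyy = np.mean((y - yc) ** 2)
    cxy = np.mean((x - xc) * (y - yc))
    lam = np.linalg.eigvalsh(np.array([[cxx, cxy], [cxy, cyy]]))
    if lam[0] <= 0:
        raise ValueError("degenerate mask: zero variance along one axis")
    minor = 4.0 * math.sqrt(float(lam[0]))
    major = 4.0 * math.sqrt(float(lam[1]))
    ecc = math.sqrt(1.0 - (minor / major) ** 2)
    return major, minor, ecc


def box_features(contour: Contour | np.ndarray) -> dict:
    """Bounding-rectangle descriptors of a contour.

    Returns the axis-aligned bounding-box ``width``/``height`` (px), the
    contour-area-to-box-area ratio, and the side lengths of the
    minimum-area (rotated) rectangle as a diagnostic.
    """
    poly = contour.vertices if isinstance(contour, Contour) else np.asarray(contour)
    area = geometry.polygon_area(poly)
    width = float(poly[:, 0].max() - poly[:, 0].min())
    height = float(poly[:, 1].max() - poly[:, 1].min())
    ratio = area / (width * height) if width > 0 and height > 0 else 1.0
    min_rect = geometry.min_area_rect_sides(poly)
    return {
        "width": width,
        "height": height,
        "area_to_bbox_ratio": ratio,
        "min_rect_long": min_rect[0],
        "min_rect_short": min_rect[1],
    }


def depth_statistics(img: DepthImage, mask: np.ndarray) -> dict:
    """Depth statistics (mm) over the non-missing masked pixels.

    Standard deviation uses the population formula (ddof 0).
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    d = img.values[m]
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all masked depth pixels are missing")
    dmax = float(d.max())
    dmin = float(d.min())
    dmean = float(d.mean())
    return {
        "depth_max": dmax,
        "depth_min": dmin,
        "depth_mean": dmean,
        "depth_range": dmax - dmin,
        "depth_sd": float(d.std(ddof=0)),
        "depth_sum": float(d.sum()),
        "dist_min_to_avg": dmean - dmin,
        "dist_max_to_avg": dmax - dmean,
    }


def approximate_volume(
    projected_area: float,
    img: DepthImage,
    mask: np.ndarray,
    contour: Contour | np.ndarray,
) -> float:
    """Approximate back volume (px²·mm).

    ``projected_area · max(contour depth) − Σ masked depths``: the depth
    reference is the maximum depth over the contour (edge) pixels, which
    for a top-view scene approximates the camera-to-ground distance, so
    the difference measures the volume of the animal's back above the
    floor.  Missing pixels are excluded from both the sum and the edge
    maximum.
    """
    poly = contour.vertices if isinstance(contour, Contour) else np.asarray(contour)
    if len(poly) < 3:
        raise ValueError("contour is empty or degenerate")
    m = np.asarray(mask, dtype=bool)
    rr = np.round(poly[:, 1]).astype(int)
    cc = np.round(poly[:, 0]).astype(int)
    edge_d = img.values[rr, cc]
    edge_d = edge_d[edge_d > 0]
    if edge_d.size == 0:
        raise ValueError("all contour pixels have missing depth")
    ref = float(edge_d.max())
    d = img.values[m]
    d = d[d > 0]
    return projected_area * ref - float(d.sum())


def _feature_dataclass():
    return [(name, float) for name in FEATURE_NAMES]


@dataclass(frozen=True)
class MorphometricFeatures:
    """The 25 named morphometric features of one instance.

    Fields f01–f16 are 2-D descriptors in px/px² (f08, f12, f13
    dimensionless), f17 is the approximate volume in px²·mm, and f18–f25
    are depth statistics in mm.  ``diagnostics`` carries auxiliary
    quantities (minimum-area-rectangle sides) that are not part of the
    feature vector.
    """

    f01_projected_area: float
    f02_contour_perimeter: float
    f03_width: float
    f04_height: float
    f05_hull_area: float
    f06_minor_axis_length: float
    f07_major_axis_length: float
    f08_eccentricity: float
    f09_hull_perimeter: float
    f10_approx_contour_area: float
    f11_approx_contour_perimeter: float
    f12_area_to_bbox_ratio: float
    f13_area_to_hull_ratio: float
    f14_defect_max: float
    f15_defect_sum: float
    f16_equiv_diameter: float
    f17_approx_volume: float
    f18_depth_max: float
    f19_depth_min: float
    f20_depth_mean: float
    f21_depth_range: float
    f22_depth_sd: float
    f23_depth_sum: float
    f24_dist_min_to_avg_depth: float
    f25_dist_max_to_avg_depth: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    names = FEATURE_NAMES

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def extract_all_features(
    img: DepthImage,
    mask: np.ndarray,
    defects_on_approx: bool = True,
    volume_area: str = "pixel_count",
) -> MorphometricFeatures:
    """Compute the full 25-feature vector for one instance.

    Parameters
    ----------
    defects_on_approx
        Compute convexity defects on the Douglas–Peucker approximate
        contour (default) rather than the raw one.
    volume_area
        ``"pixel_count"`` (default) uses the number of non-missing masked
        pixels as the discrete projected area in the volume formula;
        ``"greens"`` uses the Green's-formula contour area f01 instead.
    """
    if volume_area not in ("pixel_count", "greens"):
        raise ValueError(f"unknown volume_area mode: {volume_area!r}")
    contour = extract_contour(mask)
    poly = contour.vertices
    f01 = geometry.polygon_area(poly)
    f02 = contour.perimeter
    hull = geometry.convex_hull(poly)
    f05 = geometry.hull_area(hull)
    f09 = geometry.hull_perimeter(hull)
    approx = geometry.approx_contour(poly)
    f10 = geometry.polygon_area(approx)
    f11 = geometry.polygon_perimeter(approx)
    box = box_features(contour)
    f13 = f01 / f05
    defect_base = approx if defects_on_approx else poly
    defects = geometry.convexity_defects(defect_base, geometry.convex_hull(defect_base))
    f14 = geometry.defect_max(defects)
    f15 = geometry.defect_sum(defects)
    f16 = math.sqrt(4.0 * f01 / math.pi)
    major, minor, ecc = fit_ellipse(mask)
    stats = depth_statistics(img, mask)
    m = np.asarray(mask, dtype=bool)
    n_valid = int(np.count_nonzero(img.values[m] > 0))
    area_for_volume = float(n_valid) if volume_area == "pixel_count" else f01
    f17 = approximate_volume(area_for_volume, img, mask, contour)
    return MorphometricFeatures(
        f01_projected_area=f01,
        f02_contour_perimeter=f02,
        f03_width=box["width"],
        f04_height=box["height"],
        f05_hull_area=f05,
        f06_minor_axis_length=minor,
        f07_major_axis_length=major,
        f08_eccentricity=ecc,
        f09_hull_perimeter=f09,
        f10_approx_contour_area=f10,
        f11_approx_contour_perimeter=f11,
        f12_area_to_bbox_ratio=box["area_to_bbox_ratio"],
        f13_area_to_hull_ratio=f13,
        f14_defect_max=f14,
        f15_defect_sum=f15,
        f16_equiv_diameter=f16,
        f17_approx_volume=f17,
        f18_depth_max=stats["depth_max"],
        f19_depth_min=stats["depth_min"],
        f20_depth_mean=stats["depth_mean"],
        f21_depth_range=stats["depth_range"],
        f22_depth_sd=stats["depth_sd"],
        f23_depth_sum=stats["depth_sum"],
        f24_dist_min_to_avg_depth=stats["dist_min_to_avg"],
        f25_dist_max_to_avg_depth=stats["dist_max_to_avg"],
        diagnostics={
            "min_rect_long": box["min_rect_long"],
            "min_rect_short": box["min_rect_short"],
            "n_mask_pixels": int(m.sum()),
            "n_valid_depth_pixels": n_valid,
        },
    )
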