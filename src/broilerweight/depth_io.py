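"""Depth-image and feature-table I/O.

Depth-distance images are 2-D matrices of camera-to-surface distances in
millimetres, stored on disk as 16-bit single-channel PNG (the Z16
convention: one unsigned 16-bit integer per pixel, value 0 marking an
invalid/missing measurement).  Feature tables are plain CSV with one row
per segmented instance and a fixed, named column schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "DepthImage",
    "read_depth_z16",
    "write_depth_z16",
    "depth_to_jet",
    "read_feature_table",
    "write_feature_table",
]

#: Canonical names of the 25 morphometric features, in table order.
#: f01–f16 are 2-D shape descriptors (px / px² / dimensionless), f17 is the
#: approximate volume (px²·mm) and f18–f25 are depth statistics (mm).
FEATURE_NAMES: tuple[str, ...] = (
    "f01_projected_area",
    "f02_contour_perimeter",
    "f03_width",
    "f04_height",
    "f05_hull_area",
    "f06_minor_axis_length",
    "f07_major_axis_length",
    "f08_eccentricity",
    "f09_hull_perimeter",
    "f10_approx_contour_area",
    "f11_approx_contour_perimeter",
    "f12_area_to_bbox_ratio",
    "f13_area_to_hull_ratio",
    "f14_defect_max",
    "f15_defect_sum",
    "f16_equiv_diameter",
    "f17_approx_volume",
    "f18_depth_max",
    "f19_depth_min",
    "f20_depth_mean",
    "f21_depth_range",
    "f22_depth_sd",
    "f23_depth_sum",
    "f24_dist_min_to_avg_depth",
    "f25_dist_max_to_avg_depth",
)


@dataclass
class DepthImage:
    """A depth-distance image in millimetres.

    Parameters
    ----------
    values
        2-D array of distances (mm).  0 encodes a missing measurement.
    ground_distance
        Camera-to-ground-plane distance H in mm.  Pixels on the bare floor
        read approximately this value.
    source
        Optional path the image was loaded from.
    """

    values: np.ndarray
    ground_distance: float
    source: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(
                f"depth image must be 2-D, got {self.values.ndim} dimensions"
            )
        if np.any(self.values < 0):
            raise ValueError("depth values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of invalid (zero) pixels."""
        return self.values == 0


def write_depth_z16(img: DepthImage, path, scale: float = 1.0) -> None:
    """Write a depth image as 16-bit single-channel PNG.

    ``scale`` converts mm to stored integer units (1.0 stores whole mm;
    10.0 would store tenths of a mm).
    """
    stored = np.round(np.asarray(img.values, dtype=float) * scale)
    if stored.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("depth values exceed the uint16 range at this scale")
    iio.imwrite(str(path), stored.astype(np.uint16), extension=".png")


def read_depth_z16(path, ground_distance: float | None = None,
                   scale: float = 1.0) -> DepthImage:
    """Read a 16-bit single-channel PNG depth image.

    ``scale`` is the integer-units-per-mm factor used at write time.
    When ``ground_distance`` is omitted it is estimated as the median of
    the non-missing values (the floor dominates a top-view scene).
    """
    raw = iio.imread(str(path))
    if raw.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel image, got shape {raw.shape}"
        )
    if raw.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit depth PNG, got dtype {raw.dtype}")
    values = raw.astype(float) / scale
    if ground_distance is None:
        nonmissing = values[values > 0]
        ground_distance = float(np.median(nonmissing)) if nonmissing.size else 0.0
    return DepthImage(values=values, ground_distance=float(ground_distance),
                      source=str(path))


def depth_to_jet(img: DepthImage, dmin: float, dmax: float) -> np.ndarray:
    """Render a depth image through the classic piecewise-linear JET map.

    Depth ``dmin`` maps to dark blue, ``dmax`` to dark red; missing pixels
    are black.  Returns an (H, W, 3) uint8 RGB array.
    """
    if not dmin < dmax:
        raise ValueError(f"degenerate depth range: dmin={dmin} >= dmax={dmax}")
    d = np.asarray(img.values, dtype=float)
    t = np.clip((d - dmin) / (dmax - dmin), 0.0, 1.0)
    r = np.clip(1.5 - np.abs(4.0 * t - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * t - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * t - 1.0), 0.0, 1.0)
    rgb = np.stack([r, g, b], axis=-1)
    out = np.round(rgb * 255.0).astype(np.uint8)
    out[img.missing] = 0
    return out


def write_feature_table(records, path, weights=None) -> None:
    """Write per-instance feature rows as CSV in fixed column order.

    ``records`` is a sequence of mappings (or objects with ``to_dict``)
    containing the 25 canonical feature names; ``weights`` optionally adds
    a ``weight_kg`` column.
    """
    rows = []
    for rec in records:
        d = rec.to_dict() if hasattr(rec, "to_dict") else dict(rec)
        missing = [n for n in FEATURE_NAMES if n not in d]
        if missing:
            raise ValueError(f"record missing feature columns: {missing}")
        rows.append({n: d[n] for n in FEATURE_NAMES})
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if weights is not None:
        df["weight_kg"] = list(weights)
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV, resolving columns by name.

    Returns a DataFrame with the 25 feature columns in canonical order
    (plus ``weight_kg`` when present), regardless of on-disk column order.
    """
    df = pd.read_csv(path)
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns: {missing}")
    cols = list(FEATURE_NAMES)
    if "weight_kg" in df.columns:
        cols.append("weight_kg")
    return df[cols]
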