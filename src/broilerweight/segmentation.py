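"""Instance segmentation of birds in a depth scene.

Two routes produce the same :class:`InstanceMask` objects: a
deterministic depth-threshold segmenter (anything more than ``tau`` mm
above the ground plane, split into connected components) that is exact on
clean scenes, and an adapter contract under which an external learned
segmenter — e.g. a Mask R-CNN served outside this package — can be
plugged in interchangeably.  Downstream feature extraction does not care
which route produced a mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
from skimage import measure

from .depth_io import DepthImage

__all__ = [
    "InstanceMask",
    "threshold_segment",
    "mask_iou",
    "Segmenter",
    "SegmenterAdapter",
    "validate_instances",
]


@dataclass(frozen=True)
class InstanceMask:
    """Binary mask of one animal within a scene."""

    mask: np.ndarray
    instance_id: int

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


def _first_pixel(mask: np.ndarray) -> tuple[int, int]:
    rows, cols = np.nonzero(mask)
    return int(rows[0]), int(cols[0])


def threshold_segment(
    img: DepthImage,
    ground_distance: float | None = None,
    tau: float = 30.0,
    min_area: int = 25,
    connectivity: int = 8,
) -> list[InstanceMask]:
    """Segment foreground objects by depth threshold.

    Pixels measuring more than ``tau`` mm closer than the ground plane
    are foreground; missing pixels are never foreground.  Connected
    components smaller than ``min_area`` are discarded.  Instances are
    ordered by descending pixel count, ties broken by the raster-first
    (top-left-most) pixel, and renumbered from 0.  An empty scene yields
    an empty list.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    H = img.ground_distance if ground_distance is None else ground_distance
    fg = (img.values < H - tau) & ~img.missing
    labels = measure.label(fg, connectivity=1 if connectivity == 4 else 2)
    out = []
    for lab in range(1, int(labels.max()) + 1):
        m = labels == lab
        count = int(m.sum())
        if count < min_area:
            continue
        out.append((count, _first_pixel(m), m))
    out.sort(key=lambda t: (-t[0], t[1]))
    return [InstanceMask(mask=m, instance_id=i) for i, (_, _, m) in enumerate(out)]


def mask_iou(a: InstanceMask | np.ndarray, b: InstanceMask | np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    ma = a.mask if isinstance(a, InstanceMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, InstanceMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    union = int(np.count_nonzero(ma | mb))
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    inter = int(np.count_nonzero(ma & mb))
    return inter / union


@runtime_checkable
class Segmenter(Protocol):
    """Contract for any instance segmenter.

    ``segment`` takes a depth image and returns a list of
    :class:`InstanceMask`; outputs are validated for shape and pairwise
    disjointness before entering the pipeline.
    """

    def segment(self, img: DepthImage) -> list[InstanceMask]: ...


def validate_instances(img: DepthImage, instances: Sequence[InstanceMask],
                       min_area: int = 1) -> list[InstanceMask]:
    """Check a segmenter's output against the pipeline contract.

    Masks must match the image shape, be pairwise disjoint and meet the
    minimum area; violations raise ``ValueError``.
    """
    occupied = np.zeros(img.shape, dtype=bool)
    for inst in instances:
        if inst.shape != img.shape:
            raise ValueError(
                f"instance {inst.instance_id}: mask shape {inst.shape} does not "
                f"match image shape {img.shape}"
            )
        if inst.pixel_count < min_area:
            raise ValueError(
                f"instance {inst.instance_id}: {inst.pixel_count} px below "
                f"min_area {min_area}"
            )
        m = np.asarray(inst.mask, dtype=bool)
        if np.any(m & occupied):
            raise ValueError(
                f"instance {inst.instance_id} overlaps another instance; "
                "masks must be pairwise disjoint"
            )
        occupied |= m
    return list(instances)


class SegmenterAdapter:
    """Wrap any mask-producing callable as a validated :class:`Segmenter`.

    The callable receives the depth image and returns masks (boolean
    arrays or :class:`InstanceMask`); the adapter normalises, renumbers
    and validates them, so an external model's output is interchangeable
    with :func:`threshold_segment` downstream.
    """

    def __init__(self, fn: Callable[[DepthImage], Iterable], min_area: int = 1):
        self._fn = fn
        self.min_area = min_area

    def segment(self, img: DepthImage) -> list[InstanceMask]:
        raw = list(self._fn(img))
        instances = []
        for i, m in enumerate(raw):
            arr = m.mask if isinstance(m, InstanceMask) else np.asarray(m, dtype=bool)
            instances.append(InstanceMask(mask=arr, instance_id=i))
        return validate_instances(img, instances, min_area=self.min_area)
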