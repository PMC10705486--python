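"""Synthetic top-view depth scenes with analytic ground truth.

A scene emulates a depth camera mounted about 1 m above the floor of a
poultry house: most pixels read the camera-to-ground distance H, and each
bird carves a valley-shaped depression into that flat field.  Birds are
modelled as half-ellipsoid domes (semi-axes ``a``, ``b`` in pixels,
height ``h`` in mm) so that every downstream quantity — footprint mask,
projected area, dome volume (2/3)·π·a·b·h — has a closed form, making the
whole pipeline testable without real recordings.

Ground-truth weights follow an allometric link ``weight = c·volume·(1+ε)``
with relative noise ε, mirroring the assumption that back volume predicts
body mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .depth_io import DepthImage

__all__ = [
    "BirdSpec",
    "SceneSpec",
    "SceneTruth",
    "WeightModel",
    "analytic_halfellipsoid_volume",
    "assign_weight",
    "generate_depth_scene",
    "random_scene_spec",
    "simulate_flock",
    "DEFAULT_WEIGHT_COEF",
]

#: Default allometric coefficient c in kg per (px²·mm) of dome volume.
#: With the default bird-size distribution of :func:`random_scene_spec`
#: this spans body weights of roughly 0.85–2.35 kg, the range observed in
#: finishing broilers.
DEFAULT_WEIGHT_COEF = 1.85e-5


@dataclass(frozen=True)
class BirdSpec:
    """One half-ellipsoid dome: centre (row, col) in px, semi-axes a, b in
    px, dome height h in mm, orientation in radians (CCW from the column
    axis)."""

    center: tuple[float, float]
    a: float
    b: float
    h: float
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 3 or self.b < 3:
            raise ValueError(f"semi-axes must be >= 3 px, got a={self.a}, b={self.b}")
        if self.h <= 0:
            raise ValueError(f"dome height must be positive, got h={self.h}")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene."""

    shape: tuple[int, int] = (96, 96)
    ground_distance: float = 1000.0
    birds: tuple[BirdSpec, ...] = ()
    depth_noise_sigma: float = 0.0
    missing_pixel_rate: float = 0.0
    seed: int = 0
    disjoint: bool = True
    #: quantize rendered depths to whole mm, as a Z16 sensor would;
    #: makes the PNG round trip bit-faithful to the in-memory image
    quantize_mm: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "birds", tuple(self.birds))
        if not 0 <= self.missing_pixel_rate < 1:
            raise ValueError("missing_pixel_rate must be in [0, 1)")
        if self.depth_noise_sigma < 0:
            raise ValueError("depth_noise_sigma must be non-negative")
        for bird in self.birds:
            if bird.h >= self.ground_distance:
                raise ValueError(
                    f"dome height {bird.h} mm not below ground distance "
                    f"{self.ground_distance} mm"
                )


@dataclass(frozen=True)
class WeightModel:
    """Allometric link weight = c·volume·(1+ε), ε ~ N(0, sigma_rel)."""

    coef: float = DEFAULT_WEIGHT_COEF
    sigma_rel: float = 0.03

    def __post_init__(self) -> None:
        if self.coef <= 0:
            raise ValueError("coefficient must be positive")
        if not 0 <= self.sigma_rel < 0.5:
            raise ValueError("sigma_rel must be in [0, 0.5)")


@dataclass(frozen=True)
class SceneTruth:
    """Per-bird ground truth: footprint mask, analytic dome volume
    (px²·mm) and assigned body weight (kg)."""

    instance_id: int
    mask: np.ndarray
    analytic_volume: float
    weight: float
    weight_model: WeightModel


def analytic_halfellipsoid_volume(a: float, b: float, h: float) -> float:
    """Volume (2/3)·π·a·b·h of a half-ellipsoid dome."""
    if a <= 0 or b <= 0 or h <= 0:
        raise ValueError(f"all of a, b, h must be positive, got ({a}, {b}, {h})")
    return (2.0 / 3.0) * math.pi * a * b * h


def assign_weight(volume: float, coef: float, sigma_rel: float,
                  rng: np.random.Generator) -> float:
    """Draw a body weight for a dome volume under the allometric link.

    Resamples the (vanishingly rare) non-positive draws so weights are
    strictly positive.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if not 0 <= sigma_rel < 0.5:
        raise ValueError("sigma_rel must be in [0, 0.5)")
    base = coef * volume
    if sigma_rel == 0:
        return base
    while True:
        w = base * (1.0 + rng.normal(0.0, sigma_rel))
        if w > 0:
            return w


def _dome_height_field(spec: BirdSpec, shape: tuple[int, int]):
    """Height above ground (mm) of one dome and its closed-ellipse
    footprint mask (the rim, where the dome meets the ground, belongs to
    the footprint and reads depth exactly H)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy = rows - spec.center[0]
    dx = cols - spec.center[1]
    c, s = math.cos(spec.orientation), math.sin(spec.orientation)
    u = (dx * c + dy * s) / spec.a
    v = (-dx * s + dy * c) / spec.b
    r2 = u * u + v * v
    inside = r2 <= 1.0
    height = np.zeros(shape, dtype=float)
    height[inside] = spec.h * np.sqrt(1.0 - r2[inside])
    return height, inside


def generate_depth_scene(
    spec: SceneSpec, weight_model: WeightModel | None = None
) -> tuple[DepthImage, list[np.ndarray], list[SceneTruth]]:
    """Render a scene and its per-bird ground truth.

    Returns the depth image, one boolean footprint mask per bird, and one
    :class:`SceneTruth` per bird.  Noise is additive Gaussian in mm,
    truncated at ±3σ; missing pixels are encoded as depth 0.  The same
    spec and seed always produce bit-identical output.
    """
    if weight_model is None:
        weight_model = WeightModel()
    rng = np.random.default_rng(spec.seed)
    H = spec.ground_distance
    depth = np.full(spec.shape, H, dtype=float)
    masks: list[np.ndarray] = []
    truths: list[SceneTruth] = []
    occupied = np.zeros(spec.shape, dtype=bool)
    for i, bird in enumerate(spec.birds):
        height, mask = _dome_height_field(bird, spec.shape)
        if spec.disjoint and np.any(mask & occupied):
            raise ValueError(
                f"bird {i} overlaps a previous bird in a scene flagged disjoint"
            )
        occupied |= mask
        depth = np.where(mask, H - height, depth)
        volume = analytic_halfellipsoid_volume(bird.a, bird.b, bird.h)
        weight = assign_weight(volume, weight_model.coef, weight_model.sigma_rel, rng)
        masks.append(mask)
        truths.append(
            SceneTruth(
                instance_id=i,
                mask=mask,
                analytic_volume=volume,
                weight=weight,
                weight_model=weight_model,
            )
        )
    if spec.depth_noise_sigma > 0:
        noise = rng.normal(0.0, spec.depth_noise_sigma, size=spec.shape)
        bound = 3.0 * spec.depth_noise_sigma
        depth = depth + np.clip(noise, -bound, bound)
    if spec.missing_pixel_rate > 0:
        drop = rng.random(spec.shape) < spec.missing_pixel_rate
        depth = np.where(drop, 0.0, depth)
    depth = np.maximum(depth, 0.0)
    if spec.quantize_mm:
        depth = np.round(depth)
    img = DepthImage(values=depth, ground_distance=H)
    return img, masks, truths


def random_scene_spec(
    rng: np.random.Generator,
    seed: int,
    shape: tuple[int, int] = (96, 96),
    ground_distance: float = 1000.0,
    depth_noise_sigma: float = 2.0,
    missing_pixel_rate: float = 0.005,
    n_birds: int = 1,
) -> SceneSpec:
    """Draw a plausible single/multi-bird scene specification.

    Each bird's noiseless body weight is drawn uniformly on the
    0.87–2.35 kg range of finishing broilers; the dome volume follows
    from the default allometric coefficient, back height grows from 70
    to 105 mm with weight, and the footprint semi-axes (aspect ratio
    0.60–0.70) realise the required volume.  Heavier birds are thus both
    taller and wider, as in a real flock.
    """
    birds = []
    margin_tries = 0
    occupied: list[BirdSpec] = []
    while len(birds) < n_birds:
        w0 = rng.uniform(0.87, 2.35)
        s = (w0 - 0.87) / (2.35 - 0.87)
        volume = w0 / DEFAULT_WEIGHT_COEF
        h = 70.0 + 35.0 * s
        ratio = rng.uniform(0.60, 0.70)
        a = math.sqrt(volume / ((2.0 / 3.0) * math.pi * h * ratio))
        b = ratio * a
        reach = a + 1.0
        center = (
            rng.uniform(reach, shape[0] - 1 - reach),
            rng.uniform(reach, shape[1] - 1 - reach),
        )
        cand = BirdSpec(center=center, a=a, b=b, h=h,
                        orientation=rng.uniform(0.0, math.pi))
        if any(
            math.hypot(cand.center[0] - o.center[0], cand.center[1] - o.center[1])
            < cand.a + o.a + 2.0
            for o in occupied
        ):
            margin_tries += 1
            if margin_tries > 200:
                raise ValueError(f"could not place {n_birds} disjoint birds")
            continue
        occupied.append(cand)
        birds.append(cand)
    return SceneSpec(
        shape=shape,
        ground_distance=ground_distance,
        birds=tuple(birds),
        depth_noise_sigma=depth_noise_sigma,
        missing_pixel_rate=missing_pixel_rate,
        seed=seed,
    )


def simulate_flock(
    n_scenes: int,
    seed: int,
    weight_model: WeightModel | None = None,
    **scene_kwargs,
):
    """Generate ``n_scenes`` independent single-bird scenes.

    Yields ``(scene_index, DepthImage, masks, truths)`` tuples.  Scene
    seeds are spawned deterministically from ``seed``.
    """
    if weight_model is None:
        weight_model = WeightModel()
    master = np.random.default_rng(seed)
    for i in range(n_scenes):
        scene_seed = int(master.integers(0, 2**31 - 1))
        spec = random_scene_spec(master, seed=scene_seed, **scene_kwargs)
        img, masks, truths = generate_depth_scene(spec, weight_model)
        yield i, img, masks, truths
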