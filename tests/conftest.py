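import numpy as np
import pytest

from broilerweight import BirdSpec, SceneSpec, generate_depth_scene


@pytest.fixture
def canonical_dome():
    """Noiseless axis-aligned half-ellipsoid dome a=b=40 px, h=80 mm
    centred in a 100x100 scene, 1 m above ground."""
    spec = SceneSpec(
        shape=(100, 100),
        ground_distance=1000.0,
        birds=(BirdSpec(center=(50.0, 50.0), a=40.0, b=40.0, h=80.0),),
        depth_noise_sigma=0.0,
        missing_pixel_rate=0.0,
        seed=1,
    )
    img, masks, truths = generate_depth_scene(spec)
    return spec, img, masks, truths


@pytest.fixture
def two_dome_scene():
    """Noiseless scene with two disjoint domes of different sizes."""
    spec = SceneSpec(
        shape=(120, 180),
        ground_distance=1000.0,
        birds=(
            BirdSpec(center=(60.0, 45.0), a=30.0, b=20.0, h=90.0, orientation=0.4),
            BirdSpec(center=(55.0, 130.0), a=25.0, b=16.0, h=75.0, orientation=2.1),
        ),
        depth_noise_sigma=0.0,
        missing_pixel_rate=0.0,
        seed=7,
    )
    img, masks, truths = generate_depth_scene(spec)
    return spec, img, masks, truths


def random_blob_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """A random connected blob: union of a few overlapping discs."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    cy, cx = rng.uniform(20, shape[0] - 20), rng.uniform(20, shape[1] - 20)
    for _ in range(rng.integers(2, 5)):
        r = rng.uniform(6, 12)
        dy, dx = rng.uniform(-8, 8, size=2)
        mask |= (rows - (cy + dy)) ** 2 + (cols - (cx + dx)) ** 2 <= r**2
    return mask
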