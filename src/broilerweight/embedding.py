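"""Learned-feature contract and multi-feature fusion.

The reference pipeline extracts a 2048-dimensional activation vector per
instance from a CNN backbone (a ResNet-50 retrained for weight
regression) and concatenates it with the 25 morphometric features into a
2073-dimensional fused vector.  Training such a backbone is out of scope
here; what this module provides is

* the *contract*: any provider of finite length-2048 vectors plugs in;
* a deterministic default provider (:func:`default_embed`) that pools
  multi-scale patch statistics of the masked depth region and projects
  them to 2048 dimensions with a seeded random projection — a stand-in
  with the right interface and stable behaviour, not a trained model;
* lossless fusion/splitting of the 25 + 2048 blocks; and
* min–max (or z-score) feature normalisation fitted on training rows
  only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .depth_io import FEATURE_NAMES, DepthImage
from .morphometry import MorphometricFeatures

__all__ = [
    "EMBED_DIM",
    "FUSED_DIM",
    "Embedding",
    "FusedVector",
    "default_embed",
    "validate_embedding",
    "fuse",
    "split_fused",
    "fused_names",
    "NormalizationStats",
    "normalize_fit",
    "normalize_apply",
    "normalize_invert",
]

EMBED_DIM = 2048
FUSED_DIM = 25 + EMBED_DIM


@dataclass(frozen=True)
class Embedding:
    """A 2048-dimensional learned-feature vector for one instance."""

    values: np.ndarray
    provider_id: str = "unknown"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def validate_embedding(emb: Embedding) -> Embedding:
    """Enforce the length-2048 finite-values contract."""
    if emb.values.shape != (EMBED_DIM,):
        raise ValueError(
            f"embedding must have length {EMBED_DIM}, got shape {emb.values.shape}"
        )
    if not np.all(np.isfinite(emb.values)):
        raise ValueError("embedding contains non-finite values")
    return emb


def _patch_descriptor(region: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled multi-scale statistics of a masked depth region."""
    d = region[mask]
    lo, hi = float(d.min()), float(d.max())
    span = hi - lo if hi > lo else 1.0
    hist, _ = np.histogram(d, bins=16, range=(lo, lo + span))
    hist = hist / d.size
    moments = np.array(
        [d.mean(), d.std(), lo, hi, np.median(d),
         float(np.percentile(d, 25)), float(np.percentile(d, 75)), float(mask.mean())]
    )
    blocks = []
    for g in (4, 8):  # coarse-to-fine block means of the normalised relief
        rel = np.where(mask, (region - lo) / span, 0.0)
        r_edges = np.linspace(0, region.shape[0], g + 1).astype(int)
        c_edges = np.linspace(0, region.shape[1], g + 1).astype(int)
        for i in range(g):
            for j in range(g):
                blocks.append(
                    rel[r_edges[i]: r_edges[i + 1], c_edges[j]: c_edges[j + 1]].mean()
                )
    return np.concatenate([hist, moments, np.array(blocks)])


@lru_cache(maxsize=8)
def _projection_matrix(seed: int, base_size: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0 / np.sqrt(base_size), size=(EMBED_DIM, base_size))


def default_embed(img: DepthImage | np.ndarray, mask: np.ndarray,
                  seed: int = 0) -> Embedding:
    """Deterministic 2048-dim embedding of one masked instance.

    Multi-scale patch statistics of the masked region are projected to
    2048 dimensions by a fixed Gaussian random projection drawn from
    ``seed``; identical input and seed always give identical vectors.
    """
    values = img.values if isinstance(img, DepthImage) else np.asarray(img, float)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot embed an empty region")
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    base = _patch_descriptor(values[r0:r1, c0:c1], m[r0:r1, c0:c1])
    proj = _projection_matrix(seed, base.size)
    return validate_embedding(
        Embedding(values=proj @ base, provider_id="patch-projection", seed=seed)
    )


@dataclass(frozen=True)
class FusedVector:
    """25 morphometric + 2048 learned values, morphometric block first."""

    values: np.ndarray
    embedding_provider: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (FUSED_DIM,):
            raise ValueError(f"fused vector must have length {FUSED_DIM}, "
                             f"got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def artificial(self) -> np.ndarray:
        return self.values[: len(FEATURE_NAMES)]

    @property
    def learned(self) -> np.ndarray:
        return self.values[len(FEATURE_NAMES):]


def fused_names() -> list[str]:
    """Column names of a fused vector: Table-order feature names then
    lf_0000 … lf_2047."""
    return list(FEATURE_NAMES) + [f"lf_{i:04d}" for i in range(EMBED_DIM)]


def fuse(features: MorphometricFeatures, emb: Embedding) -> FusedVector:
    """Concatenate morphometric and learned blocks (no rescaling)."""
    validate_embedding(emb)
    return FusedVector(
        values=np.concatenate([features.to_array(), emb.values]),
        embedding_provider=emb.provider_id,
    )


def split_fused(vec: FusedVector) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`fuse`: the (25,) and (2048,) blocks."""
    return vec.artificial.copy(), vec.learned.copy()


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature statistics fitted on training rows only."""

    lo: np.ndarray
    hi: np.ndarray
    constant: np.ndarray  # boolean: features passed through unchanged
    method: str = "minmax"


def normalize_fit(X: np.ndarray, method: str = "minmax") -> NormalizationStats:
    """Fit per-feature scaling statistics on the training matrix.

    ``minmax`` maps each non-constant training column onto [0, 1];
    ``zscore`` standardises instead (lo = mean, hi = mean + sd).
    Constant columns are flagged and passed through unchanged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows × features)")
    if method == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
    elif method == "zscore":
        mu, sd = X.mean(axis=0), X.std(axis=0)
        lo, hi = mu, mu + sd
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    constant = hi == lo
    return NormalizationStats(lo=lo, hi=hi, constant=constant, method=method)


def normalize_apply(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Scale rows with training statistics; min–max output is clamped to
    [0, 1] so unseen test values cannot leave the training range."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != stats.lo.shape[0]:
        raise ValueError(
            f"row length {X.shape[1]} does not match fitted statistics "
            f"({stats.lo.shape[0]} features)"
        )
    span = np.where(stats.constant, 1.0, stats.hi - stats.lo)
    out = (X - stats.lo) / span
    if stats.method == "minmax":
        out = np.clip(out, 0.0, 1.0)
    out[:, stats.constant] = X[:, stats.constant]
    return out


def normalize_invert(Xn: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Undo :func:`normalize_apply` for non-clamped rows."""
    Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
    span = np.where(stats.constant, 1.0, stats.hi - stats.lo)
    out = Xn * span + stats.lo
    out[:, stats.constant] = Xn[:, stats.constant]
    return out
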