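"""Regression metrics and the weight-class error breakdown.

MAE = (1/n)·Σ|yᵢ − ŷᵢ|,  MSE = (1/n)·Σ(yᵢ − ŷᵢ)²,  RMSE = √MSE, and
R² = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)², with ȳ the mean observed weight.
The weight-class report splits the test range 0.85–2.35 kg into five
0.3 kg bins and reports MAE and count per bin, diagnosing whether light,
medium and heavy birds are estimated equally well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsReport",
    "WeightClassBin",
    "WeightClassReport",
    "metrics",
    "weight_class_mae",
    "WEIGHT_CLASS_EDGES",
]

#: Bin edges of the five 0.3 kg weight classes (kg).
WEIGHT_CLASS_EDGES = (0.85, 1.15, 1.45, 1.75, 2.05, 2.35)


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    mse: float
    rmse: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "mse": self.mse, "rmse": self.rmse,
                "r2": self.r2, "n": self.n}


def metrics(y, yhat) -> MetricsReport:
    """Compute MAE, MSE, RMSE and R² of predictions against truth (kg)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"y and yhat must be equal-length 1-D, got {y.shape} "
                         f"and {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssres = float(np.sum(err**2))
    if sstot == 0.0:
        if ssres == 0.0:
            r2 = 1.0
        else:
            raise ValueError("R² undefined: constant truth with nonzero residuals")
    else:
        r2 = 1.0 - ssres / sstot
    return MetricsReport(mae=mae, mse=mse, rmse=math.sqrt(mse), r2=r2, n=y.size)


@dataclass(frozen=True)
class WeightClassBin:
    lo: float
    hi: float
    mae: float
    n: int


@dataclass(frozen=True)
class WeightClassReport:
    bins: tuple[WeightClassBin, ...]
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bins": [
                {"lo": b.lo, "hi": b.hi, "mae": b.mae, "n": b.n} for b in self.bins
            ],
        }


def weight_class_mae(y, yhat, edges=WEIGHT_CLASS_EDGES,
                     overflow_bins: bool = False) -> WeightClassReport:
    """Per-weight-class MAE.

    Bins are half-open [lo, hi) with the last bin closed at both ends.
    Empty bins are absent from the report.  Truth values outside the
    range raise unless ``overflow_bins`` adds an underflow and an
    overflow bin.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    edges = tuple(edges)
    inside = (y >= edges[0]) & (y <= edges[-1])
    if not overflow_bins and not inside.all():
        bad = y[~inside]
        raise ValueError(
            f"{bad.size} weights outside [{edges[0]}, {edges[-1]}] kg; "
            "enable overflow_bins to bin them"
        )
    bins: list[WeightClassBin] = []
    if overflow_bins:
        sel = y < edges[0]
        if sel.any():
            bins.append(WeightClassBin(-math.inf, edges[0],
                                       float(np.mean(np.abs(y[sel] - yhat[sel]))),
                                       int(sel.sum())))
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        last = i == len(edges) - 2
        sel = (y >= lo) & ((y <= hi) if last else (y < hi))
        if overflow_bins and last:
            sel &= y <= hi
        if sel.any():
            bins.append(WeightClassBin(lo, hi,
                                       float(np.mean(np.abs(y[sel] - yhat[sel]))),
                                       int(sel.sum())))
    if overflow_bins:
        sel = y > edges[-1]
        if sel.any():
            bins.append(WeightClassBin(edges[-1], math.inf,
                                       float(np.mean(np.abs(y[sel] - yhat[sel]))),
                                       int(sel.sum())))
    return WeightClassReport(bins=tuple(bins), n=int(y.size))
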