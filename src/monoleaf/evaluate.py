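"""Quantitative evaluation of count predictions.

Three metrics over ground-truth integer counts :math:`y_i` and raw (unrounded)
predictions :math:`\\hat y_i`:

* RMSE: :math:`\\sqrt{\\tfrac1n \\sum_i (y_i - \\hat y_i)^2}`
* R²: :math:`1 - \\sum_i (y_i-\\hat y_i)^2 / \\sum_i (y_i-\\bar y)^2`
* accuracy: fraction of predictions whose rounded value equals the label
  exactly.  RMSE and R² use the raw predictions; only accuracy rounds.

Plus per-ground-truth prediction distributions for violin-style plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np


@dataclass
class PredictionSet:
    """Paired ground-truth counts and raw predictions."""

    y: np.ndarray
    yhat: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.yhat = np.asarray(self.yhat, dtype=float)
        if self.y.ndim != 1 or self.y.shape != self.yhat.shape:
            raise ValueError(
                f"y and yhat must be 1-D and equal length, got {self.y.shape} vs {self.yhat.shape}"
            )
        if self.y.size < 1:
            raise ValueError("need at least one prediction pair")

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def ybar(self) -> float:
        return float(self.y.mean())


def rmse(p: PredictionSet) -> float:
    """Root mean squared error of the raw predictions."""
    return float(np.sqrt(np.mean((p.y - p.yhat) ** 2)))


def r_squared(p: PredictionSet) -> float:
    """Coefficient of determination; errors when the labels are constant."""
    ss_tot = float(np.sum((p.y - p.ybar) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² is undefined for constant ground truth")
    ss_res = float(np.sum((p.y - p.yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves toward +infinity."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def accuracy(
    p: PredictionSet, rounding: Literal["half_up", "nearest_even"] = "half_up"
) -> float:
    """Fraction of predictions that round to exactly the true count."""
    if rounding == "half_up":
        rounded = round_half_up(p.yhat)
    elif rounding == "nearest_even":
        rounded = np.round(p.yhat)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return float(np.mean(rounded == p.y))


def distribution_summary(p: PredictionSet) -> dict[int, dict]:
    """Group raw predictions by true count; per-group quantiles and KDE.

    Returns ``{count: {"values", "quantiles", "median", "kde_x", "kde_y"}}``;
    the KDE entries are ``None`` for groups too small (or too degenerate) to
    estimate a density, as in a violin plot.
    """
    groups: dict[int, dict] = {}
    for count in np.unique(p.y):
        vals = np.sort(p.yhat[p.y == count])
        entry: dict = {
            "values": vals,
            "quantiles": np.quantile(vals, [0.25, 0.5, 0.75]),
            "median": float(np.median(vals)),
            "kde_x": None,
            "kde_y": None,
        }
        if vals.size >= 2 and np.ptp(vals) > 0:
            from scipy.stats import gaussian_kde

            kde = gaussian_kde(vals)
            xs = np.linspace(vals.min() - 1.0, vals.max() + 1.0, 128)
            entry["kde_x"] = xs
            entry["kde_y"] = kde(xs)
        groups[int(count)] = entry
    return groups


@dataclass
class EvalReport:
    rmse: float
    r2: float
    accuracy: float
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "accuracy": self.accuracy, "n": self.n}


def evaluate(p: PredictionSet) -> EvalReport:
    """Compute the full metric report for one prediction set."""
    return EvalReport(rmse=rmse(p), r2=r_squared(p), accuracy=accuracy(p), n=p.n)
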