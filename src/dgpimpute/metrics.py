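"""Imputation scoring: mean absolute error and Gaussian negative log likelihood.

Scores are computed over the masked (held-out) cells on the standardized
scale used for modelling; the MAE normalizes by the total number of scored
cells across variables, and the NLL is the *sum* of per-cell Gaussian
negative log densities, so it grows with the number of masked cells as
well as with miscalibration.  Methods without a predictive distribution
(LOCF) are never scored by NLL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetricResult", "mae", "nll", "score_cells"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MetricResult:
    mae: float
    nll: float | None
    n_cells: int
    per_variable: dict = field(default_factory=dict)


def mae(truth, predicted) -> float:
    """Mean absolute error over an aligned, nonempty cell set."""
    truth = np.asarray(truth, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if truth.size == 0:
        raise ValueError("cannot compute MAE on an empty cell set")
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted cell sets are not aligned")
    return float(np.mean(np.abs(truth - predicted)))


def nll(truth, mean, variance) -> float:
    """Summed Gaussian negative log likelihood of the truth values.

    Every per-cell variance must be strictly positive; a zero or negative
    variance is an error naming the offending cell.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    mean = np.asarray(mean, dtype=float).ravel()
    variance = np.asarray(variance, dtype=float).ravel()
    if truth.size == 0:
        raise ValueError("cannot compute NLL on an empty cell set")
    if not (truth.shape == mean.shape == variance.shape):
        raise ValueError("truth, mean and variance cell sets are not aligned")
    bad = np.where(variance <= 0.0)[0]
    if bad.size:
        raise ValueError(f"non-positive predictive variance at cell {bad[0]}")
    z2 = (truth - mean) ** 2 / variance
    return float(0.5 * np.sum(_LOG_2PI + np.log(variance) + z2))


def score_cells(cells: pd.DataFrame, with_nll: bool = True) -> MetricResult:
    """Score a tidy cell table with columns variable, truth, mean[, variance].

    Returns the overall MAE/NLL plus a per-variable breakdown.
    """
    if len(cells) == 0:
        raise ValueError("empty cell set")
    overall_mae = mae(cells["truth"], cells["mean"])
    overall_nll = (nll(cells["truth"], cells["mean"], cells["variance"])
                   if with_nll else None)
    per_variable = {}
    for var, grp in cells.groupby("variable"):
        per_variable[var] = MetricResult(
            mae=mae(grp["truth"], grp["mean"]),
            nll=(nll(grp["truth"], grp["mean"], grp["variance"])
                 if with_nll else None),
            n_cells=len(grp),
        )
    return MetricResult(mae=overall_mae, nll=overall_nll,
                        n_cells=len(cells), per_variable=per_variable)
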