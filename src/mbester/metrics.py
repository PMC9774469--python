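"""Surrogate-model comparison criteria: R², RMSE, MAE, MAPE, parity data.

Conventions match the study's comparison table: RMSE uses the population
divisor n, and MAPE is reported as a fraction (0.0465, not 4.65%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "score", "compare", "parity_data"]


@dataclass(frozen=True)
class MetricsReport:
    """The four comparison criteria on n paired observations.

    ``mape`` is a fraction and is ``None`` when any actual value is zero.
    """

    r2: float
    rmse: float
    mae: float
    mape: float | None
    n: int


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError(f"actual {a.shape} and predicted {p.shape} must be equal-length 1-D")
    return a, p


def score(actual, predicted) -> MetricsReport:
    """Compute R², RMSE, MAE and MAPE for paired observations.

    R² = 1 − Σ(a−p)²/Σ(a−ā)²;  RMSE = sqrt(mean (a−p)²);  MAE = mean |a−p|;
    MAPE = mean |a−p|/|a| (fraction).  Raises on zero variance in ``actual``
    (R² undefined); a zero actual value drops MAPE to ``None`` with a warning.
    """
    a, p = _paired(actual, predicted)
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("actual values have zero variance; R^2 undefined")
    err = a - p
    r2 = 1.0 - float(np.sum(err**2)) / sst
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.any(a == 0.0):
        warnings.warn("actual contains zeros: MAPE undefined, reported as None",
                      stacklevel=2)
        mape = None
    else:
        mape = float(np.mean(np.abs(err) / np.abs(a)))
    return MetricsReport(r2=r2, rmse=rmse, mae=mae, mape=mape, n=len(a))


def compare(
    report_a: MetricsReport,
    report_b: MetricsReport,
    labels: tuple[str, str] = ("RSM", "GRU"),
) -> tuple[pd.DataFrame, float, int]:
    """Side-by-side criteria table plus the MAE ratio a/b and its integer round.

    Both reports must describe the same observations (equal n).
    """
    if report_a.n != report_b.n:
        raise ValueError(f"reports disagree on n: {report_a.n} != {report_b.n}")
    table = pd.DataFrame(
        {
            "criterion": ["R2", "MAPE", "RMSE", "MAE"],
            labels[0]: [report_a.r2, report_a.mape, report_a.rmse, report_a.mae],
            labels[1]: [report_b.r2, report_b.mape, report_b.rmse, report_b.mae],
        }
    )
    ratio = report_a.mae / report_b.mae
    return table, float(ratio), int(round(ratio))


def parity_data(actual, predicted) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready parity data: (points, 45-degree reference line).

    Points carry (actual, predicted, residual = predicted − actual); the line
    spans the pooled min/max of both series.
    """
    a, p = _paired(actual, predicted)
    points = pd.DataFrame({"actual": a, "predicted": p, "residual": p - a})
    lo = float(min(a.min(), p.min()))
    hi = float(max(a.max(), p.max()))
    line = pd.DataFrame({"actual": [lo, hi], "predicted": [lo, hi]})
    return points, line
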