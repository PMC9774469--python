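"""Titration-based FFA accounting and pseudo-first-order conversion kinetics.

The acid value of an oil sample follows from a KOH back-titration,

    AV (mg KOH / g) = (FA − FB) · N · 56.11 / W ,

with FA/FB the sample/blank titrant volumes (mL), N the titrant normality
(mol/L) and W the sample mass (g).  The free-fatty-acid percentage is
FFA% = AV / 2 (oleic-acid basis), and conversion at time t is the fractional
FFA consumed, X = 100 · (ffa0 − ffa_t)/ffa0.

Conversion–time series are modeled as pseudo-first-order in the oil's FFA:
X(t) = 100 · (1 − exp(−k_obs · t)), fitted through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KOH_MW",
    "TitrationRecord",
    "ConversionSeries",
    "acid_value",
    "ffa_percent",
    "conversion",
    "fit_first_order",
    "predict_conversion",
    "reduce_titrations",
]

KOH_MW = 56.11  # g/mol, molar mass of KOH


@dataclass(frozen=True)
class TitrationRecord:
    """One KOH titration: sample volume FA, blank FB (mL), normality N
    (mol/L), sample mass W (g), sampling time t (min)."""

    FA: float
    FB: float
    N: float
    W: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.FB < 0 or self.FA < self.FB:
            raise ValueError(
                f"require FA >= FB >= 0, got FA={self.FA}, FB={self.FB}"
            )
        if self.N <= 0 or self.W <= 0:
            raise ValueError("N and W must be strictly positive")


@dataclass
class ConversionSeries:
    """A conversion–time series with its feed FFA content."""

    t: np.ndarray          # minutes
    X: np.ndarray          # conversion, %
    ffa0: float = 32.5     # feed FFA content, % (microalgae oil feed)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.t.shape != self.X.shape or self.t.ndim != 1:
            raise ValueError("t and X must be equal-length 1-D arrays")
        if np.any((self.X < 0) | (self.X > 100)):
            raise ValueError("conversions must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t, "conversion_pct": self.X})


def acid_value(rec: TitrationRecord) -> float:
    """Acid value (mg KOH per g sample) from one titration record."""
    return (rec.FA - rec.FB) * rec.N * KOH_MW / rec.W


def ffa_percent(av: float) -> float:
    """FFA content (%) from the acid value: AV/2 on the oleic-acid basis."""
    if av < 0:
        raise ValueError(f"acid value must be non-negative, got {av}")
    return av / 2.0


def conversion(ffa0: float, ffa_t: float) -> float:
    """Conversion (%) of FFA into ester: 100·(ffa0 − ffa_t)/ffa0."""
    if ffa0 <= 0:
        raise ValueError("feed FFA must be strictly positive")
    if not 0 <= ffa_t <= ffa0:
        raise ValueError(
            f"ffa_t = {ffa_t} outside [0, ffa0 = {ffa0}]: negative conversion"
        )
    return 100.0 * (ffa0 - ffa_t) / ffa0


def fit_first_order(t, X) -> float:
    """Observed pseudo-first-order constant k_obs (1/min), origin-constrained.

    Least squares of −ln(1 − X/100) on t through the origin:
    k = Σ t·y / Σ t².  Exact first-order data is reproduced to round-off;
    a single point reduces to the closed form k = −ln(1 − X/100)/t.

    Raises
    ------
    ValueError
        if no usable points remain or any conversion reaches 100%.
    """
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    if t.shape != X.shape or t.ndim != 1:
        raise ValueError("t and X must be equal-length 1-D arrays")
    if np.any(X >= 100.0):
        raise ValueError("conversion at saturation (>= 100%): first-order fit undefined")
    mask = t > 0
    if not np.any(mask):
        raise ValueError("need at least one point with t > 0")
    y = -np.log(1.0 - X[mask] / 100.0)
    tt = t[mask]
    return float(np.sum(tt * y) / np.sum(tt * tt))


def predict_conversion(k_obs: float, t) -> float | np.ndarray:
    """First-order conversion X(t) = 100·(1 − exp(−k_obs·t)), in %."""
    if k_obs < 0:
        raise ValueError("k_obs must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    X = 100.0 * (1.0 - np.exp(-k_obs * t_arr))
    return float(X) if np.isscalar(t) else X


def reduce_titrations(
    records: list[TitrationRecord], ffa0: float | None = None
) -> ConversionSeries:
    """Reduce raw titration records to a conversion–time series.

    ``ffa0`` defaults to the FFA implied by the earliest record (the feed).
    """
    if not records:
        raise ValueError("no titration records supplied")
    recs = sorted(records, key=lambda r: r.t)
    ffa = [ffa_percent(acid_value(r)) for r in recs]
    if ffa0 is None:
        ffa0 = ffa[0]
    X = np.array([conversion(ffa0, f) for f in ffa])
    return ConversionSeries(
        t=np.array([r.t for r in recs]), X=X, ffa0=float(ffa0)
    )
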