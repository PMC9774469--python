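"""Three-factor Box-Behnken designs and coded/natural factor conversion.

A Box-Behnken design (BBD) for three factors places runs at the twelve edge
midpoints of the factor cube — every pair of factors at the four (±1, ±1)
combinations with the third factor at its midpoint — plus replicated centre
runs.  Coded units map a factor's low/mid/high settings to −1/0/+1 by the
usual linear scaling, so the quadratic response surface is fitted on a
near-orthogonal basis.

The study emulated here varies three esterification factors: the
oil-to-methanol molar ratio multiplier (1:5 … 1:25), the p-TSA catalyst
loading (0 … 5 wt% of oil), and the reaction time (10 … 90 min), with five
centre replicates for a 17-run design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "PAPER_FACTORS",
    "build_bbd",
    "to_coded",
    "to_natural",
    "InvalidFactorError",
    "UnsupportedDesignError",
]


class InvalidFactorError(ValueError):
    """A factor specification violates low < high."""


class UnsupportedDesignError(ValueError):
    """Requested a design this module does not generate (only 3-factor BBD)."""


@dataclass(frozen=True)
class FactorSpec:
    """One continuous design factor with its natural-unit range.

    Coded −1 maps to ``low``, +1 to ``high`` and 0 to the midpoint.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidFactorError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


#: Factor ranges of the semi-pilot microbubble esterification study:
#: oil:MeOH molar-ratio multiplier 5–25, catalyst 0–5 wt%, time 10–90 min.
PAPER_FACTORS: tuple[FactorSpec, FactorSpec, FactorSpec] = (
    FactorSpec("molar_ratio", 5.0, 25.0, "MeOH per oil, mol/mol"),
    FactorSpec("catalyst_wt_pct", 0.0, 5.0, "wt% of oil"),
    FactorSpec("time_min", 10.0, 90.0, "min"),
)


def to_coded(value: float, factor: FactorSpec) -> float:
    """Convert a natural-unit setting to coded units: (value − mid)/half-range.

    Values outside [low, high] are permitted (extrapolation) but flagged with
    a warning.
    """
    coded = (value - factor.mid) / factor.half_range
    if abs(coded) > 1.0 + 1e-12:
        warnings.warn(
            f"value {value} lies outside the range of factor {factor.name!r} "
            f"[{factor.low}, {factor.high}]; coded value {coded:.4g} extrapolates",
            stacklevel=2,
        )
    return coded


def to_natural(coded: float, factor: FactorSpec) -> float:
    """Inverse of :func:`to_coded`: mid + coded × half-range."""
    return factor.mid + coded * factor.half_range


# Edge midpoints in lexicographic factor-pair order (AB, AC, BC), each pair
# swept (−1,−1), (−1,+1), (+1,−1), (+1,+1); the held-out factor sits at 0.
_EDGE_PATTERNS: tuple[tuple[float, float, float], ...] = tuple(
    tuple(
        (a if k == i else b if k == j else 0.0) for k in range(3)
    )
    for (i, j) in ((0, 1), (0, 2), (1, 2))
    for a in (-1.0, 1.0)
    for b in (-1.0, 1.0)
)

_CODED_COLUMNS = ("A_coded", "B_coded", "C_coded")
RESPONSE_COLUMN = "conversion_pct"


@dataclass
class DesignTable:
    """An ordered run table: coded settings, natural settings, optional response.

    Backed by a :class:`pandas.DataFrame` with columns ``run_id``,
    ``A_coded``/``B_coded``/``C_coded``, one natural column per factor name,
    and optionally ``conversion_pct``.
    """

    frame: pd.DataFrame
    factors: tuple[FactorSpec, FactorSpec, FactorSpec] = field(default=PAPER_FACTORS)

    def __post_init__(self) -> None:
        if self.frame["run_id"].duplicated().any():
            raise ValueError("run_ids must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, 3) array of coded factor settings."""
        return self.frame[list(_CODED_COLUMNS)].to_numpy(dtype=float)

    @property
    def natural(self) -> np.ndarray:
        return self.frame[[f.name for f in self.factors]].to_numpy(dtype=float)

    @property
    def has_responses(self) -> bool:
        return RESPONSE_COLUMN in self.frame.columns

    @property
    def responses(self) -> np.ndarray:
        if not self.has_responses:
            raise ValueError("design table carries no responses")
        return self.frame[RESPONSE_COLUMN].to_numpy(dtype=float)

    def with_responses(self, values: Sequence[float]) -> "DesignTable":
        """Return a copy of the table with the response column set."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self),):
            raise ValueError(f"expected {len(self)} responses, got {values.shape}")
        frame = self.frame.copy()
        frame[RESPONSE_COLUMN] = values
        return DesignTable(frame, self.factors)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        factors: tuple[FactorSpec, FactorSpec, FactorSpec] = PAPER_FACTORS,
    ) -> "DesignTable":
        frame = pd.read_csv(path)
        required = {"run_id", *_CODED_COLUMNS}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design CSV missing columns: {sorted(missing)}")
        return cls(frame, factors)


def build_bbd(
    factors: Sequence[FactorSpec],
    n_center: int = 5,
    shuffle_seed: int | None = None,
) -> DesignTable:
    """Generate the 3-factor Box-Behnken design with ``n_center`` centre runs.

    Runs are ordered deterministically: the 12 edge midpoints in lexicographic
    factor-pair order, then the centre replicates.  Pass ``shuffle_seed`` to
    randomize the run order reproducibly (run order is irrelevant to the OLS
    fit but matters on the bench).

    Raises
    ------
    UnsupportedDesignError
        if the number of factors is not exactly 3.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"Box-Behnken generator supports exactly 3 factors, got {len(factors)}"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    coded = np.array(_EDGE_PATTERNS + ((0.0, 0.0, 0.0),) * n_center)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(coded))
        coded = coded[order]

    frame = pd.DataFrame(
        {
            "run_id": np.arange(1, len(coded) + 1),
            "A_coded": coded[:, 0],
            "B_coded": coded[:, 1],
            "C_coded": coded[:, 2],
        }
    )
    for k, f in enumerate(factors):
        frame[f.name] = to_natural(coded[:, k], f)  # vectorized: pure arithmetic
    return DesignTable(frame, factors)
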