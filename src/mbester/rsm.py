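"""Quadratic response-surface fitting, ANOVA, prediction and optimization.

The response surface is the full second-order polynomial in coded units,

    y = b0 + bA·A + bB·B + bC·C + bAB·AB + bAC·AC + bBC·BC
        + bAA·A² + bBB·B² + bCC·C² ,

fitted by ordinary least squares on a Box-Behnken design.  The module also
ships the coefficients reported for the semi-pilot microbubble esterification
of microalgae oil (conversion % as a function of coded molar ratio, catalyst
loading and time), which serve as the generating model for synthetic tables.

Conventions
-----------
* RMSE = sqrt(SSE / n) — the population convention, which is the scale on
  which the study's surrogate-comparison metrics are quoted.
* ANOVA uses partial (Type-III) sums of squares for per-term F tests; on the
  orthogonal coded BBD the linear and interaction terms coincide with
  sequential SS.  Lack of fit is tested against pure error from replicated
  points.
* Predictions are plain polynomial evaluations — not clipped to [0, 100] —
  unless ``clip=True`` is requested.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import PAPER_FACTORS, DesignTable, FactorSpec, to_coded

__all__ = [
    "QuadraticModel",
    "FitDiagnostics",
    "OptimumReport",
    "REFERENCE_MODEL",
    "TERM_NAMES",
    "fit_quadratic",
    "predict",
    "anova",
    "model_hierarchy",
    "optimize_response",
    "perturbation_profiles",
    "SingularFitError",
]

TERM_NAMES = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2")


class SingularFitError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class QuadraticModel:
    """Full quadratic surface in coded units; response in % conversion."""

    b0: float
    bA: float
    bB: float
    bC: float
    bAB: float
    bAC: float
    bBC: float
    bAA: float
    bBB: float
    bCC: float
    factor_specs: tuple[FactorSpec, FactorSpec, FactorSpec] = field(
        default=PAPER_FACTORS
    )

    @property
    def coefficients(self) -> np.ndarray:
        """The 10 coefficients in basis order [1, A, B, C, AB, AC, BC, A², B², C²]."""
        return np.array(
            [self.b0, self.bA, self.bB, self.bC, self.bAB, self.bAC, self.bBC,
             self.bAA, self.bBB, self.bCC]
        )

    @property
    def hessian(self) -> np.ndarray:
        """Hessian of the surface (constant for a quadratic)."""
        return np.array(
            [
                [2 * self.bAA, self.bAB, self.bAC],
                [self.bAB, 2 * self.bBB, self.bBC],
                [self.bAC, self.bBC, 2 * self.bCC],
            ]
        )

    @property
    def gradient_at_origin(self) -> np.ndarray:
        return np.array([self.bA, self.bB, self.bC])

    def coded_point(self, natural: tuple[float, float, float]) -> np.ndarray:
        """Code a natural-unit operating point against the attached factor specs."""
        return np.array(
            [to_coded(v, f) for v, f in zip(natural, self.factor_specs)]
        )

    def to_dict(self) -> dict:
        d = {name: float(c) for name, c in zip(TERM_NAMES, self.coefficients)}
        d["factors"] = [
            {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
            for f in self.factor_specs
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        factors = tuple(
            FactorSpec(f["name"], f["low"], f["high"], f.get("units", ""))
            for f in d.get("factors", [])
        ) or PAPER_FACTORS
        coeffs = [float(d[name]) for name in TERM_NAMES]
        return cls(*coeffs, factor_specs=factors)  # type: ignore[arg-type]


#: Quadratic conversion surface reported for the semi-pilot microbubble
#: esterification study (coded units; response in % FFA conversion).
REFERENCE_MODEL = QuadraticModel(
    b0=88.68, bA=3.27, bB=26.13, bC=7.97,
    bAB=3.24, bAC=3.49, bBC=3.98,
    bAA=-1.74, bBB=-29.76, bCC=-5.81,
)


@dataclass(frozen=True)
class FitDiagnostics:
    r2: float
    adj_r2: float
    rmse: float
    residuals: np.ndarray


def design_matrix(coded: np.ndarray) -> np.ndarray:
    """Expand (n, 3) coded settings into the 10-column quadratic basis."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    A, B, C = coded[:, 0], coded[:, 1], coded[:, 2]
    return np.column_stack(
        [np.ones_like(A), A, B, C, A * B, A * C, B * C, A * A, B * B, C * C]
    )


def predict(
    model: QuadraticModel,
    coded: np.ndarray | tuple[float, float, float],
    clip: bool = False,
) -> float | np.ndarray:
    """Evaluate the quadratic at coded point(s); warns when extrapolating.

    Returns a scalar for a single point, an array for a batch.
    """
    arr = np.atleast_2d(np.asarray(coded, dtype=float))
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        warnings.warn(
            "prediction point lies outside the coded cube [-1, 1]^3 "
            "(extrapolation beyond the design region)",
            stacklevel=2,
        )
    y = design_matrix(arr) @ model.coefficients
    if clip:
        y = np.clip(y, 0.0, 100.0)
    return float(y[0]) if np.ndim(coded) == 1 or isinstance(coded, tuple) else y


def _ols(X: np.ndarray, y: np.ndarray, names: tuple[str, ...]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10 * len(y)]
        raise SingularFitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'undetermined'}"
        )
    return sm.OLS(y, X).fit()


def fit_quadratic(table: DesignTable) -> tuple[QuadraticModel, FitDiagnostics]:
    """OLS fit of the full 10-term quadratic to a design table with responses."""
    y = table.responses
    if len(y) < 10:
        raise ValueError(f"need at least 10 runs with responses, got {len(y)}")
    X = design_matrix(table.coded)
    res = _ols(X, y, TERM_NAMES)
    model = QuadraticModel(*res.params, factor_specs=table.factors)
    sse = float(np.sum(res.resid**2))
    diag = FitDiagnostics(
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        rmse=float(np.sqrt(sse / len(y))),
        residuals=np.asarray(res.resid),
    )
    return model, diag


def _pure_error(coded: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pure-error SS and df from exact replicate groups of coded settings."""
    groups: dict[tuple, list[float]] = {}
    for row, yi in zip(coded, y):
        groups.setdefault(tuple(np.round(row, 10)), []).append(float(yi))
    ss = sum(
        float(np.sum((np.asarray(v) - np.mean(v)) ** 2))
        for v in groups.values()
        if len(v) > 1
    )
    df = sum(len(v) - 1 for v in groups.values())
    return ss, df


def anova(model: QuadraticModel, table: DesignTable) -> pd.DataFrame:
    """ANOVA with per-term partial (Type-III) SS and a lack-of-fit split.

    Rows: Model, the nine terms, Residual, Lack of fit, Pure error, Total.
    Model SS + Residual SS = Total SS; LOF SS + PE SS = Residual SS.  The
    lack-of-fit rows are omitted (with a warning) when the design has no
    replicated points.
    """
    y = table.responses
    X = design_matrix(table.coded)
    res = _ols(X, y, TERM_NAMES)
    n = len(y)
    sse = float(np.sum(res.resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    ssm = sst - sse
    df_model, df_resid = 9, n - 10
    ms_resid = sse / df_resid if df_resid > 0 else np.nan

    rows = []

    def f_p(ss: float, df: int, ms_denom: float, df_denom: int):
        if df <= 0 or not np.isfinite(ms_denom) or ms_denom <= 0:
            return np.nan, np.nan
        f = (ss / df) / ms_denom
        return f, float(stats.f.sf(f, df, df_denom))

    f, p = f_p(ssm, df_model, ms_resid, df_resid)
    rows.append(("Model", ssm, df_model, ssm / df_model, f, p))

    # Type-III: SS of each term = SSE without it minus SSE of the full model.
    for j, name in enumerate(TERM_NAMES[1:], start=1):
        Xr = np.delete(X, j, axis=1)
        sse_r = float(np.sum(sm.OLS(y, Xr).fit().resid ** 2))
        ss_j = sse_r - sse
        f, p = f_p(ss_j, 1, ms_resid, df_resid)
        rows.append((name, ss_j, 1, ss_j, f, p))

    rows.append(("Residual", sse, df_resid, ms_resid, np.nan, np.nan))

    ss_pe, df_pe = _pure_error(table.coded, y)
    if df_pe > 0:
        ss_lof = sse - ss_pe
        df_lof = df_resid - df_pe
        ms_pe = ss_pe / df_pe
        f, p = f_p(ss_lof, df_lof, ms_pe, df_pe)
        rows.append(("Lack of fit", ss_lof, df_lof,
                     ss_lof / df_lof if df_lof > 0 else np.nan, f, p))
        rows.append(("Pure error", ss_pe, df_pe, ms_pe, np.nan, np.nan))
    else:
        warnings.warn(
            "no replicated design points: lack-of-fit rows omitted", stacklevel=2
        )

    rows.append(("Total", sst, n - 1, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["source", "sum_sq", "df", "mean_sq", "F", "p"]
    )


_HIERARCHY = {
    "linear": slice(0, 4),
    "linear+interactions": slice(0, 7),
    "full quadratic": slice(0, 10),
}


def model_hierarchy(table: DesignTable) -> list[tuple[str, float]]:
    """Adjusted R² of the nested linear / two-factor-interaction / quadratic fits.

    Returns all three classes ranked best-first by adjusted R², the standard
    goodness-of-fit summary used to justify the quadratic surface.
    """
    y = table.responses
    X = design_matrix(table.coded)
    out = []
    for name, sl in _HIERARCHY.items():
        res = sm.OLS(y, X[:, sl]).fit()
        out.append((name, float(res.rsquared_adj)))
    return sorted(out, key=lambda t: t[1], reverse=True)


@dataclass(frozen=True)
class OptimumReport:
    coded: np.ndarray
    natural: np.ndarray
    predicted: float
    location: str  # "interior stationary" or "boundary"
    concave: bool  # Hessian negative semidefinite?


def optimize_response(
    model: QuadraticModel,
    maximize: bool = True,
) -> OptimumReport:
    """Exact box-constrained optimum of the quadratic over the coded cube.

    Enumerates all 27 face patterns of [−1,1]³ (each coordinate free, at −1,
    or at +1), solves the stationary point of the free coordinates in closed
    form, and keeps feasible candidates plus the vertices.  For a quadratic
    this is exhaustive and exact.  Ties are broken by predicted response,
    then lexicographic coded order.  Non-concave directions are reported via
    ``concave``, not raised.
    """
    H = model.hessian
    sign = 1.0 if maximize else -1.0
    candidates: list[np.ndarray] = []
    for pattern in itertools.product((-1.0, 1.0, None), repeat=3):
        free = [k for k, v in enumerate(pattern) if v is None]
        x = np.array([0.0 if v is None else v for v in pattern])
        if free:
            # stationary point of the free block: H_ff x_f = -(g_f + H_fc x_c)
            Hff = H[np.ix_(free, free)]
            fixed = [k for k in range(3) if k not in free]
            rhs = -(
                model.gradient_at_origin[free]
                + (H[np.ix_(free, fixed)] @ x[fixed] if fixed else 0.0)
            )
            try:
                xf = np.linalg.solve(Hff, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(np.abs(xf) > 1.0 + 1e-12):
                continue
            x[free] = np.clip(xf, -1.0, 1.0)
        candidates.append(x)

    values = [sign * predict_quiet(model, c) for c in candidates]
    best = max(
        range(len(candidates)),
        key=lambda i: (values[i], tuple(-candidates[i])),
    )
    x_opt = candidates[best]
    interior = bool(np.all(np.abs(x_opt) < 1.0 - 1e-12))
    eig = np.linalg.eigvalsh(H)
    natural = np.array(
        [f.mid + c * f.half_range for c, f in zip(x_opt, model.factor_specs)]
    )
    return OptimumReport(
        coded=x_opt,
        natural=natural,
        predicted=float(predict_quiet(model, x_opt)),
        location="interior stationary" if interior else "boundary",
        concave=bool(np.all(eig <= 1e-12)),
    )


def predict_quiet(model: QuadraticModel, coded) -> float:
    """Polynomial evaluation without the extrapolation warning (internal use)."""
    arr = np.atleast_2d(np.asarray(coded, dtype=float))
    return float((design_matrix(arr) @ model.coefficients)[0])


def perturbation_profiles(
    model: QuadraticModel,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_points: int = 41,
) -> pd.DataFrame:
    """One-factor-at-a-time response traces through ``center`` (coded units).

    Long-format plot-ready table with columns factor, coded, response — the
    data behind a perturbation plot.
    """
    grid = np.linspace(-1.0, 1.0, n_points)
    frames = []
    for k, name in enumerate(("A", "B", "C")):
        pts = np.tile(np.asarray(center, dtype=float), (n_points, 1))
        pts[:, k] = grid
        y = design_matrix(pts) @ model.coefficients
        frames.append(pd.DataFrame({"factor": name, "coded": grid, "response": y}))
    return pd.concat(frames, ignore_index=True)
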