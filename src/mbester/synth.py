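"""Seeded synthetic-data generators for the study's unpublished raw inputs.

The semi-pilot esterification study reports its fitted models and summary
statistics but not the underlying raw tables (the 17-run design responses,
the rate-constant-vs-temperature series behind the Arrhenius plot, or the
titration sheets).  These generators emulate each input from the published
quantities so the full analysis pipeline can be exercised end to end:

* design responses drawn from the published quadratic surface plus Gaussian
  noise at the published residual scale (RMSE 3.0832 %),
* Arrhenius rate constants at 70/80/90 °C from EA = 10.01 kJ/mol with
  lognormal noise,
* pseudo-first-order conversion–time curves calibrated to 97% at 40 min,
* titration records constructed by inverting the acid-value/FFA equations
  along a conversion curve from the 32.5% FFA feed.

Each generator draws from its own fixed substream of the master seed
(``SeedSequence(seed, spawn_key=(stream,))``), so adding or reordering
generator calls never perturbs the others.  Zero-noise output is exactly
invertible by the corresponding analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import KOH_MW, ConversionSeries, TitrationRecord
from .design import PAPER_FACTORS, DesignTable, FactorSpec, build_bbd
from .kinetics import R_GAS
from .rsm import QuadraticModel, REFERENCE_MODEL, design_matrix

__all__ = [
    "ArrheniusConfig",
    "TimecourseConfig",
    "AssayConfig",
    "SynthConfig",
    "gen_response_table",
    "gen_rate_constants",
    "gen_timecourse",
    "gen_titrations",
]

# fixed substream ids: adding a generator must not perturb existing streams
_STREAM_TABLE, _STREAM_RATES, _STREAM_TIMECOURSE, _STREAM_TITRATION = 0, 1, 2, 3

#: k_obs calibrated so that X(40 min) = 97%: −ln(0.03)/40 per minute.
DEFAULT_K_OBS = -float(np.log(0.03)) / 40.0


@dataclass(frozen=True)
class ArrheniusConfig:
    """Generating Arrhenius law: EA in kJ/mol over the 70–90 °C window.

    ``lnA0`` defaults to EA·1000/(R·343.15), i.e. k(70 °C) = 1 in arbitrary
    units — only EA matters to the fit.  ``lognoise_sd`` is the σ of additive
    Gaussian noise on ln k (≈ fractional noise on k); the default 0.004 makes
    the fitted EA standard error ≈ 0.3 kJ/mol on the three-temperature design,
    the precision the study reports for its 10.01 ± 0.3 estimate.
    """

    EA: float = 10.01
    T: tuple[float, ...] = (343.15, 353.15, 363.15)
    lnA0: float | None = None
    lognoise_sd: float = 0.004

    def __post_init__(self) -> None:
        if len(set(self.T)) != len(self.T):
            raise ValueError("temperatures must be distinct")
        if self.lognoise_sd < 0:
            raise ValueError("lognoise_sd must be >= 0")

    @property
    def lnA0_value(self) -> float:
        if self.lnA0 is not None:
            return self.lnA0
        return self.EA * 1000.0 / (R_GAS * 343.15)


@dataclass(frozen=True)
class TimecourseConfig:
    """First-order conversion curve on a 10-min sampling grid over 0–60 min."""

    k_obs: float = DEFAULT_K_OBS
    t: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.k_obs < 0 or self.noise_sd < 0:
            raise ValueError("k_obs and noise_sd must be >= 0")


@dataclass(frozen=True)
class AssayConfig:
    """Titration conditions: feed FFA 32.5%, 0.5 N KOH, 1 g samples."""

    ffa0: float = 32.5
    N: float = 0.5
    W: float = 1.0
    FB: float = 0.1

    def __post_init__(self) -> None:
        if min(self.ffa0, self.N, self.W) <= 0 or self.FB < 0:
            raise ValueError("ffa0, N, W must be > 0 and FB >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Master configuration for all generators (one seed, split per stream)."""

    seed: int = 0
    noise_sd_response: float = 3.0832
    generating_model: QuadraticModel = REFERENCE_MODEL
    n_center: int = 5
    clip_responses: bool = False
    factors: tuple[FactorSpec, FactorSpec, FactorSpec] = field(
        default=PAPER_FACTORS
    )
    arrhenius: ArrheniusConfig = field(default_factory=ArrheniusConfig)
    timecourse: TimecourseConfig = field(default_factory=TimecourseConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)

    def __post_init__(self) -> None:
        if self.noise_sd_response < 0:
            raise ValueError("noise_sd_response must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


def gen_response_table(cfg: SynthConfig) -> DesignTable:
    """17-run Box-Behnken table with responses from the generating quadratic.

    Responses are the surface evaluated at the coded design points plus
    iid Gaussian noise with σ = ``noise_sd_response``; ``clip_responses``
    optionally clamps to [0, 100].
    """
    table = build_bbd(cfg.factors, n_center=cfg.n_center)
    mean = design_matrix(table.coded) @ cfg.generating_model.coefficients
    noise = cfg.rng(_STREAM_TABLE).normal(0.0, cfg.noise_sd_response, len(mean))
    y = mean + noise
    if cfg.clip_responses:
        y = np.clip(y, 0.0, 100.0)
    return table.with_responses(y)


def gen_rate_constants(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """(T, k) series from the generating Arrhenius law with lognormal noise."""
    a = cfg.arrhenius
    T = np.asarray(a.T, dtype=float)
    ln_k = a.lnA0_value - a.EA * 1000.0 / (R_GAS * T)
    if a.lognoise_sd > 0:
        ln_k = ln_k + cfg.rng(_STREAM_RATES).normal(0.0, a.lognoise_sd, len(T))
    return T, np.exp(ln_k)


def gen_timecourse(cfg: SynthConfig) -> ConversionSeries:
    """Pseudo-first-order conversion–time curve, optionally with noise.

    Noise is truncated so conversions stay in [0, 100] and X(0) remains 0.
    """
    tc = cfg.timecourse
    t = np.asarray(tc.t, dtype=float)
    X = 100.0 * (1.0 - np.exp(-tc.k_obs * t))
    if tc.noise_sd > 0:
        noise = cfg.rng(_STREAM_TIMECOURSE).normal(0.0, tc.noise_sd, len(t))
        noise[t == 0] = 0.0
        X = np.clip(X + noise, 0.0, 100.0)
    return ConversionSeries(t=t, X=X, ffa0=cfg.assay.ffa0)


def gen_titrations(
    cfg: SynthConfig, series: ConversionSeries | None = None
) -> list[TitrationRecord]:
    """Titration records whose assay reduction reproduces ``series`` exactly.

    Inverts FFA% = AV/2 and the acid-value equation: each conversion X(t)
    implies ffa_t = ffa0·(1 − X/100), AV = 2·ffa_t, and a sample titrant
    volume FA = FB + AV·W/(N·56.11).  The construction is exact (no noise),
    so the zero-noise round trip holds to round-off.
    """
    if series is None:
        series = gen_timecourse(cfg)
    a = cfg.assay
    records = []
    for t, X in zip(series.t, series.X):
        ffa_t = series.ffa0 * (1.0 - X / 100.0)
        av = 2.0 * ffa_t
        FA = a.FB + av * a.W / (a.N * KOH_MW)
        records.append(TitrationRecord(FA=FA, FB=a.FB, N=a.N, W=a.W, t=float(t)))
    return records
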