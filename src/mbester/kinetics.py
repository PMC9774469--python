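"""Film-theory gas–liquid reaction kinetics and Arrhenius analysis.

Models the methanol-microbubble / oil system with two-film theory: a methanol
vapor bubble dissolving into the liquid and reacting with protonated free
fatty acid.  The module provides

* empirical solubility correlations (methanol-in-oil, at 25 °C and corrected
  to temperature T),
* the liquid-film mass-transfer coefficient for sub-2-mm bubbles,
* the Hatta number Ha = sqrt(M·k·Cb)/k_bl comparing reaction to film
  diffusion, with its enhancement factors (Danckwerts finite-Ei correction
  E = Ha·(1 − (Ha−1)/(2·Ei)) and instantaneous ceiling
  Ei = 1 + M·Cb/(Hb·Pg)),
* regime classification (Ha > 1 ⇒ reaction at the bubble surface; E ≈ Ha ⇒
  pseudo-first-order behaviour),
* the two-film series-resistance absorption rate and the lumped rate law
  −r_A = k_r·(P_A·101325)·Cb, and
* Arrhenius activation-energy estimation by OLS of ln k on 1/T.

Several of the source correlations circulate with ambiguous typography; each
function documents the algebraic reading adopted here, and alternate readings
can be supplied via the ``form`` hooks where noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "G_ACCEL",
    "ATM_PA",
    "PhysicalProps",
    "FilmKineticsState",
    "ArrheniusFit",
    "REFERENCE_PROPS",
    "solubility_25",
    "solubility_T",
    "film_coefficient",
    "hatta",
    "enhancement_instantaneous",
    "enhancement",
    "classify",
    "lumped_rate",
    "series_resistance_rate",
    "fit_arrhenius",
    "evaluate_film_state",
]

R_GAS = 8.314          # J/(mol K)
G_ACCEL = 9.81         # m/s^2
ATM_PA = 101_325.0     # Pa per atm


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class PhysicalProps:
    """Physical property set for the film-kinetics calculations.

    Correlation inputs (``Vl``, ``Vg``, ``mu_l``) are taken in the units of
    the cited source correlations; everything else is SI (K, Pa, m, s, kmol).
    The default values are the constants quoted for the semi-pilot microbubble
    esterification study: kg_sigma = 5.32e−3, k_bl = 1.24e−4 m/s, Hb = 43.05.
    """

    T: float = 343.15            # K (70 degC)
    Vl: float = 1.0              # liquid molar volume, correlation units
    Vg: float = 1.0              # gas molar volume, correlation units
    mu_l: float = 0.0276         # liquid viscosity, Pa s (microalgae oil, 40 degC)
    rho_l: float = 920.0         # liquid density, kg/m^3
    D_gl: float = 1.0e-9         # gas-in-liquid diffusivity, m^2/s
    # The study quotes its derived constants but not the (M_gl, k, Cb) inputs
    # behind them; these defaults are a representative set consistent with its
    # qualitative regime (Ha just above 1: surface reaction, E tracking Ha).
    M_gl: float = 1.7e-6         # solubility correlation output
    Cb: float = 1.0              # bulk FFA concentration, kmol/m^3
    Pg: float = ATM_PA           # gas partial pressure, Pa
    PA: float = 1.0              # gas partial pressure, atm
    Hb: float = 43.05            # solubility/Henry constant (quoted value)
    kg_sigma: float = 5.32e-3    # gas-side coefficient (quoted value)
    k_bl: float = 1.24e-4        # liquid-film coefficient, m/s (quoted value)
    k: float = 1.0e-2            # intrinsic pseudo-first-order rate constant
    kr: float = 1.32e-5          # lumped rate constant (quoted value)
    g: float = G_ACCEL

    def __post_init__(self) -> None:
        _require_positive(
            T=self.T, Vl=self.Vl, Vg=self.Vg, mu_l=self.mu_l, rho_l=self.rho_l,
            D_gl=self.D_gl, M_gl=self.M_gl, Cb=self.Cb, Pg=self.Pg,
            Hb=self.Hb, kg_sigma=self.kg_sigma, k_bl=self.k_bl, k=self.k,
            kr=self.kr,
        )

    def validity_warnings(self) -> list[str]:
        out = []
        if not 273.0 <= self.T <= 400.0:
            out.append(f"T = {self.T} K is outside the correlation range [273, 400]")
        return out


#: Property set with the constants quoted for the semi-pilot study.
REFERENCE_PROPS = PhysicalProps()


@dataclass(frozen=True)
class FilmKineticsState:
    """Derived film-theory state: Hatta number, enhancements, regime, rate."""

    Ha: float
    Ei: float
    E: float
    regime: str              # "surface" or "bulk"
    order_assessment: str    # "pseudo-first-order" or "other"
    rate: float              # kmol/(m^3 s)


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k = −EA/(R·T) + ln A0 fitted by OLS of ln k on 1/T."""

    EA: float          # kJ/mol
    lnA0: float
    r2: float
    EA_stderr: float   # kJ/mol

    def k_at(self, T: float | np.ndarray) -> float | np.ndarray:
        return np.exp(self.lnA0 - self.EA * 1000.0 / (R_GAS * np.asarray(T, float)))


def solubility_25(Vl: float, mu_l: float, Vg: float) -> float:
    """Gas-in-liquid solubility correlation at 25 °C.

    Adopted reading: 6.02e−5 · Vl^0.36 · mu_l^0.61 · Vg^0.64 (all exponents
    positive; inputs in the source correlation's units).
    """
    _require_positive(Vl=Vl, mu_l=mu_l, Vg=Vg)
    return 6.02e-5 * Vl**0.36 * mu_l**0.61 * Vg**0.64


def solubility_T(M25: float, T: float) -> float:
    """Temperature correction of the 25 °C solubility:
    M(T) = 4.996e3 · M25 · exp(−2539/T).

    Self-consistent at 25 °C: the factor 4996·exp(−2539/298.15) = 1.0005.
    """
    _require_positive(M25=M25, T=T)
    return 4.996e3 * M25 * np.exp(-2539.0 / T)


def film_coefficient(D_gl: float, rho_l: float, mu_l: float, g: float = G_ACCEL) -> float:
    """Liquid-film mass-transfer coefficient for bubbles under 2 mm:
    k_bl = 0.31 · (D² · ρ · g / μ)^(1/3).
    """
    _require_positive(D_gl=D_gl, rho_l=rho_l, mu_l=mu_l)
    return 0.31 * (D_gl**2 * rho_l * g / mu_l) ** (1.0 / 3.0)


def hatta(M_glT: float, k: float, Cb: float, k_bl: float) -> float:
    """Hatta number, pseudo-first-order form: Ha = sqrt(M·k·Cb) / k_bl.

    M_glT here plays the role of the interfacial diffusive capacity in the
    adopted reading of the study's grouping; k = 0 gives Ha = 0.
    """
    _require_positive(M_glT=M_glT, Cb=Cb, k_bl=k_bl)
    if k < 0:
        raise ValueError("rate constant k must be non-negative")
    return float(np.sqrt(M_glT * k * Cb) / k_bl)


def enhancement_instantaneous(M_glT: float, Cb: float, Hb: float, Pg: float) -> float:
    """Instantaneous-reaction enhancement ceiling: Ei = 1 + M·Cb/(Hb·Pg)."""
    _require_positive(Cb=Cb, Hb=Hb, Pg=Pg)
    if M_glT < 0:
        raise ValueError("M_glT must be non-negative")
    return 1.0 + M_glT * Cb / (Hb * Pg)


def enhancement(Ha: float, Ei: float, warn: bool = True) -> float:
    """Finite-Ei enhancement factor (Danckwerts-style):
    E = Ha · (1 − (Ha − 1)/(2·Ei)).

    At Ha = 1 the correction vanishes (E = 1); as Ei → ∞, E → Ha (fast
    pseudo-first-order limit).  A result below 1 lies outside the
    approximation's validity and is flagged, not raised.
    """
    if Ha < 0 or Ei < 1:
        raise ValueError("require Ha >= 0 and Ei >= 1")
    E = Ha * (1.0 - (Ha - 1.0) / (2.0 * Ei))
    if warn and E < 1.0:
        import warnings

        warnings.warn(
            f"enhancement E = {E:.4g} < 1: outside the approximation's validity range",
            stacklevel=2,
        )
    return float(E)


def classify(Ha: float, E: float, pfo_tolerance: float = 0.1) -> tuple[str, str]:
    """Regime and order assessment from (Ha, E).

    Reaction at the bubble surface iff Ha > 1, otherwise in the bulk; the
    reaction is assessed pseudo-first-order when E tracks Ha within the
    relative tolerance (default 10%, for 'E and Ha almost equal').
    """
    regime = "surface" if Ha > 1.0 else "bulk"
    if Ha > 0 and abs(E - Ha) / Ha <= pfo_tolerance:
        order = "pseudo-first-order"
    else:
        order = "other"
    return regime, order


def lumped_rate(PA: float, Cb: float, kr: float = 1.32e-5) -> float:
    """Lumped overall rate law: −r_A = kr · (PA · 101325) · Cb.

    ``PA`` in atm (converted to Pa internally), ``Cb`` in kmol/m³; ``kr``
    defaults to the study's quoted lumped constant.
    """
    if PA < 0 or Cb < 0:
        raise ValueError("PA and Cb must be non-negative")
    return kr * (PA * ATM_PA) * Cb


def series_resistance_rate(
    kg_sigma: float, Ha: float, D_glT: float, k: float, Cb: float, Pg: float
) -> float:
    """Two-film series-resistance absorption rate.

    Adopted reading: −r_A = Pg / (1/kgσ + Ha/sqrt(D·k·Cb)) — gas-side and
    reaction-enhanced liquid-side resistances in series.  The liquid term
    vanishes as the reaction becomes infinitely fast, leaving the gas-side
    limit kgσ·Pg.  Interpretation-dependent; see module docstring.
    """
    _require_positive(kg_sigma=kg_sigma, D_glT=D_glT, k=k, Cb=Cb, Pg=Pg)
    if Ha < 0:
        raise ValueError("Ha must be non-negative")
    return Pg / (1.0 / kg_sigma + Ha / np.sqrt(D_glT * k * Cb))


def evaluate_film_state(props: PhysicalProps) -> FilmKineticsState:
    """Full film-theory evaluation from a property set.

    Uses the quoted k_bl / kg_sigma / Hb of the property set directly (they
    are measured/quoted constants, not recomputed from the correlations).
    """
    M_T = props.M_gl
    Ha = hatta(M_T, props.k, props.Cb, props.k_bl)
    Ei = enhancement_instantaneous(M_T, props.Cb, props.Hb, props.Pg)
    E = enhancement(Ha, Ei, warn=False)
    regime, order = classify(Ha, E)
    rate = lumped_rate(props.PA, props.Cb, props.kr)
    return FilmKineticsState(Ha=Ha, Ei=Ei, E=E, regime=regime,
                             order_assessment=order, rate=rate)


def fit_arrhenius(T, k) -> ArrheniusFit:
    """Estimate the activation energy by OLS of ln k on 1/T.

    EA = −slope · R, reported in kJ/mol with the slope's standard error
    propagated.  Exact on exactly-Arrhenius data.

    Raises
    ------
    ValueError
        for fewer than 2 distinct temperatures or non-positive rate constants.
    """
    T = np.asarray(T, dtype=float)
    k = np.asarray(k, dtype=float)
    if T.shape != k.shape or T.ndim != 1:
        raise ValueError("T and k must be equal-length 1-D arrays")
    if len(np.unique(T)) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    if np.any(k <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and rate constants must be positive")
    res = stats.linregress(1.0 / T, np.log(k))
    EA = -res.slope * R_GAS / 1000.0
    stderr = (res.stderr or 0.0) * R_GAS / 1000.0
    return ArrheniusFit(
        EA=float(EA),
        lnA0=float(res.intercept),
        r2=float(res.rvalue**2),
        EA_stderr=float(stderr),
    )
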