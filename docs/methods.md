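# Methods

This note records the models implemented in `mbester`, their assumptions,
the defaults and why, and the design choices made where the published
account of the semi-pilot microbubble esterification analysis left the
design genuinely open.

## Design and response surface

The three-factor Box-Behnken design places 12 runs at the edge midpoints of
the coded cube (each factor pair at (±1, ±1), the third factor at 0) plus
replicated centre runs — 17 runs with the study's five centre replicates.
Factors and ranges: oil:MeOH molar-ratio multiplier 5–25 (stored numerically;
"1:N" is display only), p-TSA catalyst 0–5 wt% of oil, time 10–90 min.
Coding is the standard linear map (value − mid)/half-range. Run order is
deterministic (factor-pair lexicographic, centres last) with an optional
seeded shuffle, since the original run order is unknown and irrelevant to
OLS.

The surface is the full 10-term quadratic in coded units, fitted by OLS
(statsmodels). Conventions, each deliberate:

- **RMSE = √(SSE/n)** (population divisor), the scale on which the study's
  comparison criteria are quoted; the ANOVA's mean squares use the usual
  df divisors.
- **ANOVA** reports partial (Type-III) SS per term, F-tested against the
  residual MS; lack of fit is split from pure error using exact replicate
  groups (4 df from 5 centre points). On this design the linear and
  interaction columns are mutually orthogonal, so their partial SS equal
  sequential SS; the three pure-quadratic columns are correlated with each
  other after centering, so per-term SS additivity is only guaranteed at the
  Model-row level (model SS + residual SS = total SS), which is what the
  table asserts.
- **Optimization** of a quadratic over the cube is solved exactly by
  enumerating the 27 face patterns of [−1,1]³ (each coordinate free or
  pinned at ±1), solving each free block's stationary point in closed form
  and keeping feasible candidates; ties break by predicted value then
  lexicographic coded order. No iterative optimizer, no tolerance knobs.
  For the reference surface the unconstrained stationary point lies outside
  the cube (time coordinate ≈ 2.08), so the in-cube maximizer is a boundary
  point, *not* the interior operating point the study validated — the
  operating point is therefore handled as an explicit evaluation, not an
  optimization result.
- Predictions are unclipped by default (the fitted quadratic exceeds 100 %
  in parts of the cube); a `clip` flag bounds them to [0, 100] for display.
- p-values come from the F distribution with no multiplicity correction
  (none is standard in single-response DOE practice).

## GRU surrogate

The cell implements the bias-free gate equations (reset, candidate, update,
convex-combination state) with a linear readout; an optional flag adds
standard bias vectors. Each design run is a length-1 sequence whose input is
the coded factor triple — the natural encoding for tabular DOE data, which
needs no further input scaling since coded factors already live in [−1, 1].
With h₀ = 0 the recurrent maps W_r, U_r, W, W_z carry no gradient; they are
retained for fidelity to the cell equations and verified to have exactly
zero gradient.

Training keeps the study's hyperparameters verbatim — 50 hidden units,
global gradient-norm clipping at 0.1, initial learning rate 0.01 dropped by
a factor 0.2 every 100 epochs, 150 epochs — but the study names no loss,
optimizer, target scaling or initialization. The package's choices:

- **Loss**: mean-squared error, the default for scalar regression.
- **Targets standardized** (zero mean, unit variance over the training
  table), un-scaled at prediction time. Raw-percent targets put the readout
  on a ~10²–10³ scale that no clipped-gradient trainer can reach in 150
  epochs.
- **Optimizer**: full-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) under the
  step-decay schedule, with clipping applied to the raw gradient before the
  Adam update. Plain gradient descent under a 0.1 clip and 0.01 learning
  rate can move the parameter vector at most clip·lr·epochs = 0.15 in norm
  over the whole run — structurally unable to fit the response scale — so a
  per-parameter adaptive method is the only trainer consistent with the
  published epoch budget.
- **Initialization**: Glorot-uniform gate matrices from the seeded
  generator; readout starts at zero (initial prediction = training mean).
- **Evaluation is in-sample** on all 17 runs: the study reports fit quality,
  not a held-out split, and 17 points leave no meaningful validation set.

Training is pure numpy, bitwise reproducible given (seed, hyperparameters,
table). Analytic gradients are verified against central finite differences
to ≤ 1e-4 relative error.

## Comparison metrics

R² = 1 − SSE/SST, RMSE = √(SSE/n), MAE, and MAPE reported **as a fraction**
(the study prints 0.0465, not 4.65 %). MAPE is undefined when any actual
value is zero and is then reported absent with a warning. The comparison
emits the criteria side by side plus the MAE ratio and its integer rounding;
parity data carries (actual, predicted, residual) with the 45° line spanning
the pooled range.

## Film-theory kinetics

Two-film gas–liquid theory for methanol microbubbles dissolving into
catalyst-charged oil. The published renditions of the solubility, Hatta,
enhancement and rate groupings circulate with damaged typography, so each
function documents the canonical algebraic reading it adopts:

- solubility at 25 °C: 6.02e-5 · V_l^0.36 · μ_l^0.61 · V_g^0.64 (inputs in
  the source correlation's units);
- temperature correction: M(T) = 4.996e3 · M₂₅ · exp(−2539/T) — note
  4996·exp(−2539/298.15) = 1.0005, i.e. the correlation is self-consistent
  at 25 °C;
- liquid-film coefficient (bubbles < 2 mm): k_bl = 0.31·(D²ρg/μ)^⅓;
- Hatta number, pseudo-first-order form: Ha = √(M·k·C_b)/k_bl;
- instantaneous enhancement: E_i = 1 + M·C_b/(H_b·P_g);
- finite-E_i enhancement (Danckwerts-style): E = Ha·(1 − (Ha−1)/(2E_i)),
  exact limits E(Ha=1) = 1 and E → Ha as E_i → ∞; E < 1 is flagged as
  outside the approximation's validity;
- series-resistance absorption rate: −r_A = P_g/(1/k_gσ + Ha/√(D·k·C_b));
- lumped rate law: −r_A = k_r·(P_A·101325)·C_b with k_r = 1.32e-5.

Regime rules: reaction at the bubble surface iff Ha > 1; pseudo-first-order
iff |E − Ha|/Ha ≤ 0.1 (the study says the two are "almost equal" without a
number; 10 % is the package's threshold). The quoted constants k_gσ =
5.32e-3, k_bl = 1.24e-4 m/s, H_b = 43.05 and k_r = 1.32e-5 ship as the
reference property set. The property inputs behind the study's Ha (M, k,
C_b) are not published; the defaults (M = 1.7e-6, k = 1e-2, C_b = 1
kmol/m³) are a representative set consistent with its qualitative findings —
Ha just above 1 and E tracking Ha — and are not estimates of the true values.

**Arrhenius**: OLS of ln k on 1/T (scipy linregress); E_A = −slope·R in
kJ/mol with the slope's standard error propagated. Exact on exactly-Arrhenius
data; unbiased under additive ln-noise (the estimator is linear in the
noise, which the test suite exploits by measuring bias with antithetic
noise pairs instead of at the Monte-Carlo noise floor).

## Titration assay

AV = (F_A − F_B)·N·56.11/W; FFA % = AV/2 — the standard oleic-acid-basis
factor (the halving convention is stated prominently because printed
versions of the formula are easily misread as a ×12 factor). Conversion is
defined on FFA percent. The conversion–time model is pseudo-first-order with
X(0) = 0 enforced: k_obs is fitted through the origin on −ln(1 − X/100) vs
t, which reduces to the closed form k = −ln(1 − X/100)/t for a single point.
The three-regime slope structure visible in such curves is deliberately not
parameterized (a piecewise fit of a 7-point curve would be decoration, not
inference).

## Synthetic-data generators

The generators emulate the study's unpublished raw inputs; their defaults
are the study's stated conditions:

| quantity | default | source |
|---|---|---|
| response noise σ | 3.0832 % | the published RSM residual scale (best available proxy for replicate noise) |
| generating surface | the published quadratic | — |
| E_A | 10.01 kJ/mol | published estimate |
| rate temperatures | 343.15/353.15/363.15 K | the 70–90 °C window |
| ln A° | E_A/(R·343.15) | normalizes k(70 °C)=1; only E_A matters to the fit |
| ln k noise σ | 0.004 | makes the fitted E_A standard error ≈ 0.3 kJ/mol, the published ± precision |
| k_obs | −ln(0.03)/40 = 0.08766 min⁻¹ | calibrated to the published 97 % at 40 min |
| sampling grid | 0–60 min by 10 | the study's 10-min sampling interval |
| feed FFA, N, W | 32.5 %, 0.5 N, 1 g | feed characterization; standard titration practice |

Noise models: Gaussian on responses (optionally clipped to [0, 100]),
lognormal on rate constants (positivity), truncated Gaussian on conversions
with X(0) pinned to 0. Titration sheets are built by exact inversion of the
assay equations along a conversion curve, so the zero-noise synth → assay
round trip is exact to round-off. Each generator draws from its own fixed
`SeedSequence(seed, spawn_key=(stream,))` substream, so adding or reordering
generator calls never perturbs another generator's output.

**What the synthetic data does not emulate:** real replicate structure
(noise is iid, not run-order- or level-dependent), any model bias (responses
are generated *from* the quadratic, so the refit is consistent by
construction), drift, or measurement error in the titration volumes. Passing
tests therefore demonstrate that the estimators recover known generating
parameters under the stated noise — not that the published models describe
the real reactor.

## Problem sizes and determinism

Everything is small by nature: 17-run tables, 3-point rate series, 7-point
time courses, 150-epoch full-batch training (< 1 s). The Monte-Carlo
recovery studies use 200–1000 seeded replicates. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; pipelines re-run
byte-identically for a fixed seed.

## Known limitations

- The quadratic surface is empirical: it exceeds 100 % conversion near the
  high-A/high-C boundary, and its in-cube maximizer is not the operating
  point the study validated (that point is not a stationary point of the
  published surface; whatever desirability settings produced it were not
  published, so no agreement is forced).
- The GRU's in-sample superiority over the quadratic on 17 points is an
  expressiveness statement (~450 effective parameters vs 10), not evidence
  of generalization.
- The film-theory state depends on property inputs the study did not
  publish; only the regime classification, not the numeric Ha, should be
  compared.
- Correlation-based solubility and film coefficients carry the usual
  engineering-correlation uncertainty and unit conventions of their sources.
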