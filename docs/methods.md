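# Methods

This note records the modeling assumptions behind `metacage`, the defaults
that matter, why they have the values they do, and what the synthetic-data
generator does and does not emulate. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Protocol and units

One calorimetry session is an overnight fast (cage entry 18:00, no food,
water ad libitum) followed by a fixed 60 kJ test meal at 10:00 (high-
carbohydrate, HC, or high-fat, HF) and recording until 17:00. All internal
time is seconds relative to meal delivery; analysis uses 15-min meal-anchored
bins, a pre-meal (basal) window of −120..0 min and a post-meal window of
0..300 min. Gas rates are mL/min at 5-s sampling; energy rates are Watts;
energies kJ; masses g.

## Chamber model and washout inversion

The chamber is modeled as a single well-mixed compartment: measured
concentration-derived rates are the first-order low-pass response of the
animal's production with time constant τ = dilution volume / flow
(10.5 L / 1.5 L·min⁻¹ = 7 min). The generator discretizes this exactly under
a zero-order hold. The analysis inverts it as m(t) + τ·dm/dt with the
derivative taken on a 30-s moving-average copy (nearest-edge padding):
wide enough to keep the differentiation noise bounded, narrow enough that
the fastest physiological transients of interest (minutes) are untouched.
Samples within one smoothing width of a missing gap are also marked missing
(guard band), since their smoothed derivative mixes interpolated values.
The inversion amplifies analyzer noise by design; the state-space stage is
what removes it.

## State-space decomposition

Per gas channel a two-state random-walk model with scalar observations
y(k) = rest(k) + cost(k)·a(k) + e(k). The VO₂ and VCO₂ channels share the
activity regressor but are otherwise independent, so the four-state problem
factorizes exactly into two two-state filters (the observation matrix is
block diagonal); this is an implementation identity, not an approximation.

Defaults, chosen as engineering values and exposed in the API:

- process noise: q_rest = 0.01 mL·min⁻¹ per sample, q_cost = 0.001 per
  sample — resting metabolism drifts on the hour scale, the cost of activity
  is near-constant within a session;
- observation noise: estimated per channel from the first 10 valid minutes
  as 1.4826 × MAD of residuals against a 30-s moving average (robust to
  bursts in the estimation window); an explicit value can be supplied;
- initialization: rest states at the median of the first 10 minutes with a
  (2 mL/min)² prior, cost states at 0 with a wide (1 (mL/min/AU)²) prior;
- missing samples: the filter predicts through gaps without update, so the
  state variance inflates naturally;
- fixed-interval (RTS) smoothing is the default; a causal filter-only mode
  exists for on-line use;
- after smoothing, resting states are floored at 10⁻³ mL/min and cost states
  at 0 (gas rates cannot be negative; a negative cost estimate is noise).

Act-RQ is the ratio of two small cost states and is masked wherever activity
falls below the 5th percentile of nonzero activity — below that the ratio is
numerically meaningless. Bins with more than 50% missing samples are flagged
and excluded from window statistics.

The filter is validated against an independent sliding-window least-squares
oracle (regression of gas on activity): on noise-free piecewise-constant
sessions the two agree to within 1%, and on generator output the recovered
per-activity-unit cost is within 5% of truth where activity is present.

## Session parameters

- **BMR**: mean resting EE over the clean bins of the −120..0 min window
  (the mean, not the minimum: the fasted pre-meal trace is stationary enough
  that the windowed mean is the better-conditioned estimator).
- **TEF**: net AUC of (RMR − BMR) over 0..300 min, trapezoidal on bin-mid
  values with the first/last clean values held to the window edges; negative
  excursions subtract. TEF is a property of the meal, not the animal's size,
  and is therefore never normalized to body composition.
- **Gox/Lox**: the nitrogen-free two-fuel partition printed above; the two
  formulas sum to the Weir EE within 0.5% over RQ ∈ [0.70, 1.00] (tested as
  a coefficient identity), so the partition conserves energy.
- **Normalization**: value × 300/(FFM + 0.2·FM), applied to BMR/RMR-like
  rates only. FFM and FM are interpolated linearly and independently between
  the bracketing imaging days (never extrapolated past the second), and the
  interpolation is validated by regressing predicted (FFM+FM) against the
  weight measured on session days.

## Diet arithmetic

Energy densities use 16.7 kJ/g for carbohydrate (starch + sucrose) and
protein and 37.7 kJ/g for fat; minerals, vitamins, cellulose and choline are
non-metabolizable. The food quotient is the energy-fraction weighted sum
with weights 1.0 / 0.825 / 0.7 (carbohydrate / protein / fat). Known
last-digit inconsistencies in the source table are preserved and kept
visible rather than resolved silently:

- recomputing density from the g/kg recipes gives 15.92 / 19.80 kJ/g where
  the labels print 15.95 / 19.82; the label values are used for meal-mass
  bookkeeping (60 kJ of HF = 3.0 g), the recomputed values are reported
  alongside (`computed_*` properties);
- the HCD food quotient is 0.946 by the label fractions (0.9459 from the
  recipe); a differently-stated value of 0.955 circulates for the same diet
  and is not reproducible from either route, so 0.946 is used throughout;
- 60 kJ of HC at the label density is 3.8 g; meal records elsewhere print
  3.9 g. The printed mass is treated as a meal-record constant, not derived.

## The synthetic cohort (stated world)

Defaults encode the emulated study's reported quantities as ground truth;
quantities the study does not report are set once to physiologically
plausible values for young male Wistar rats on 3-week diet blocks and not
revisited:

| quantity | default | origin |
|---|---|---|
| cohort size | 24 | reported design |
| start body weight | 303.3 ± 24.5 g | reported mean; SD from SEM 5.0 × √24 |
| start adiposity | 10 ± 2.5 % | chosen (typical for ~10-week Wistar) |
| HCD adiposity gain | 2.0 ± 1.5 pp | chosen (moderate gain, wide spread) |
| HFD adiposity gain | 6.0 ± 2.0 pp | chosen (larger gain under fat) |
| inter-diet gain correlation | 0.482 | reported |
| BW-gain / adiposity-gain coupling | 0.911 (HFD), 0.525 (HCD) | reported |
| BW gain | 84 ± 15 g (HCD), 100 ± 20 g (HFD) | from reported ~4–5 g/day |
| visceral:subcutaneous medians | 1.44 / 1.82 / 1.53 | reported |
| ratio lognormal σ | 0.22 | back-solved from the reported ±0.27 half-IQR at median 1.82 |

Adiposity gains are drawn from a bivariate normal; BW gains are constructed
with the target Pearson coupling to the adiposity gains (noise orthogonalized
so the per-cohort sample r concentrates on the target). Composition at each
imaging point is derived from (BW, adiposity), so FFM = BW − FM holds exactly
and plain weighings fluctuate by 1.5 g around the piecewise-linear BW
trajectory (imaging-day weights are exact, which makes the interpolation
identity testable). An optional arrival screen (keep the 2 leanest + 2
fattest of each incoming group of 8) reproduces the variance-inflating
selection of the emulated design; it is off by default. Adiposity "gain" is
the difference in percentage points, the definition consistent with using a
single slope covariate in the mixed model.

## The synthetic session (stated world)

- basal resting EE 1.5 W per 300 g metabolic mass, scaled as (MM/300)^0.75;
  basal Rest-RQ 0.80 (overnight-fasted);
- resting drift: random walks on log-EE (2×10⁻⁴ per sample) and RQ
  (5×10⁻⁵ per sample) — a few percent of slow wander per session;
- thermic effect: a gamma rise–decay kernel (shape 2, scale 60 min)
  normalized so its integral over 0..300 min equals tef_fraction × meal
  energy exactly (10% × 60 kJ = 6 kJ by default); energy conservation of
  this bump is a tested invariant (<0.1%);
- RQ excursion: the same kernel normalized to a stated mean rise over the
  post-meal window. HC meals: 0.06 + 0.0086 per percentage point of HCD
  adiposity gain — the carbohydrate-sensitivity mechanism, under which
  upper-half gainers peak above the diet's food quotient of 0.946 while
  resistant rats stay below it; HF meals: a flat 0.035. Latent RQ is clipped
  to [0.65, 1.0] (whole-body RQ above 1 would imply net lipogenesis, which
  the emulated setting excludes);
- activity: Poisson bursts (12/h) with lognormal magnitude (median 15 AU,
  σ=0.5) and exponential duration (mean 60 s); cost 10 mW per activity unit,
  ×1.25 after the meal; the muscles' fuel mix tracks the resting mix +0.02;
- measurement: exact first-order chamber response, additive Gaussian
  analyzer noise (0.05 mL/min per channel), and a 300-s acquisition freeze
  at meal delivery stored as missing records, never zeros.

**What the generator does not emulate** — circadian structure beyond the
fast/refeed design, thermoregulatory EE (the protocol's 26 °C makes it
negligible), meal-size dependence of TEF, correlated analyzer drift,
behavioral bout structure beyond a marked point process, and any
within-rat correlation between sessions beyond shared body composition.
A green recovery test therefore establishes that the pipeline is unbiased
under first-order chamber physics and uncorrelated noise; it cannot certify
robustness to analyzer drift or to model-mismatched cage dynamics.

## Mixed-effects model

`mp ~ adchg * mealtime` with nested random intercepts (rat / session /
period), fitted by REML. When each period contributes one aggregated value —
the standard case, one pre- and one post-meal mean per session — the
period-level intercept is statistically confounded with the residual and is
merged into it; the full three-level structure engages automatically when
per-bin replication is present. With one session per rat the session level
is likewise absorbed by the rat intercept. Fixed-effect p-values are Wald
(normal approximation) by default with an optional residual-df t reference;
adchg enters uncentered (this affects only the intercept's meaning). The
optimizer falls back from L-BFGS to Powell/BFGS, which handle variance
estimates on the zero boundary; non-converged, singular or rank-deficient
fits are returned flagged, never silently replaced. HC and HF meals, and
HCD vs HFD adiposity changes, are always separate models, and no
multiple-testing correction is applied (significant: P ≤ 0.01; marginal:
0.01 < P ≤ 0.05).

For estimator calibration the model world can be simulated directly
(`simulate_meal_response`). Its default dispersion scales are back-solved
from the reported standard errors of the pre-meal slope (0.0041) and the
interaction (0.0086 ± 0.0026) at n = 24 and an adchg SD of 1.5 pp:
SE(interaction) = √(2σ_w²/Σ(x−x̄)²) gives within-period σ_w = 0.0132, and
SE(adchg) = √((σ_b²+σ_w²)/Σ(x−x̄)²) gives between-rat σ_b = 0.0264. The
fitted SEs reproduce both (tested), so the simulated world is on the same
information scale as the emulated study.

## Numerical conventions and degenerate inputs

- quartiles (for median ± 0.5·IQR displays) by linear interpolation
  (type-7, the numpy default);
- median-split ties straddling the boundary are resolved by stable input
  order with a warning; the split always returns exactly n/2 + n/2;
- identical paired samples in the Wilcoxon comparison return p = 1 rather
  than an error (no shift is the correct reading);
- pointwise t-tests skip timepoints with zero variance in both groups,
  flagging them;
- Pearson correlation refuses n < 3, non-finite values and zero variance;
- activity identically zero makes the cost states unidentifiable: they stay
  at their prior and the result is flagged (with Act-RQ fully masked);
- all-missing traces, non-uniform grids, traces shorter than the smoothing
  window, overlapping analysis windows and infeasible correlation targets
  raise immediately with specific messages.

## Determinism

Every stochastic stage takes a seed; the pipeline derives per-stage child
seeds (all < 2³¹) from one master seed via `numpy.random.SeedSequence`.
Two runs of the same configuration produce byte-identical CSV/JSON bundles,
and every bundle carries a provenance record (configuration hash excluding
output paths, seeds, package versions).

## Known limitations

- The chamber inversion assumes a single well-mixed compartment with known
  τ; multi-compartment cages or flow drift would bias the recovered
  transients.
- TEF uses a fixed 300-min window; meals whose thermic response outlasts the
  window are truncated by design.
- The Gox/Lox partition is nitrogen-free (no protein-oxidation correction).
- Wald p-values are anti-conservative relative to the conditional-t
  reference at small n; the residual-df option narrows but does not close
  that gap.
- The final composition point may come from dissection rather than imaging;
  the schema carries it identically and does not model method differences.
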