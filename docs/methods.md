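# Methods

## The twitch curve

A single contraction is modeled as a bell-shaped force transient determined
by six measured parameters (peak force; lead, half-contraction,
contraction, half-relaxation and total-duration times).  The construction
uses the kernel `g(u) = u·e^(1−u)` on normalized time `u = (t −
T_lead)/T_c`, in three pieces joined at the peak and at the
half-relaxation point:

* rise, `u ∈ (0, 1]`: `f = F_max · g(u)^k1`, `k1` solved so the curve
  passes through `F_max/2` at `T_hc`;
* early relaxation, `u ∈ (1, T_hr/T_c]`: `f = F_max · g(u)^k2`, `k2`
  solved for `F_max/2` at `T_hr`;
* tail, `u ∈ (T_hr/T_c, T_tw/T_c]`: `f = (F_max/2) ·
  (g(u)/g(u_hr))^k3`, `k3` solved so the force is `10⁻⁴·F_max` at
  `T_tw` (the standard "force decays to 0.01% of the peak" definition of
  the twitch duration).

Because `g(u)^k = 0.5` is log-linear in `k`, all three exponents have
closed forms (`k = log(target)/log g(u_anchor)`), so every anchor holds to
machine precision; `g(1) = 1` and the tail rescaling make the curve
continuous, and `g'(1) = 0` makes the peak smooth.  The curve is exactly
unimodal (each piece is monotone) and is truncated to zero beyond `T_tw`,
leaving a deliberate 10⁻⁴-relative step there rather than an artificial
taper.  A zero peak force is accepted as a "silent" contraction — the
representation of an amplitude clamped at zero (below).

This construction is this package's own realization of the published
anchor definitions; the original analytical form from the source
literature is not restated in the data available here, so any curve
satisfying the six anchors with a smooth bell shape is admissible.  All
quantities are in ms and mN, and every model equation uses only
dimensionless ratios.

## Prediction rules

With `x = F_tetmin/F_max(1)` (starting force normalized to the first
twitch amplitude):

* amplitude: `F_max(i) = (1 + cot α · x) · F_max(1)`, clamped at zero by
  default (the `F_max(i) ≥ 0` constraint); at `α = 90°` the cotangent is
  computed as exactly 0, so amplitudes are bit-identical to `F_max(1)`;
* contraction time: `T_c(i) = (1.04 + 0.274·x) · T_c(1)`;
* half-relaxation time: `T_hr(i) = (2.397 + 0.3509·x) · T_c(1)` — note
  both lines multiply `T_c(1)`;
* `T_hc` and `T_tw` scale proportionally with `T_c(i)` and `T_hr(i)`;
* the lead time is constant across the train.

A contraction starting at `F_tetmin = 0` (a fully relaxed unit) reproduces
the first twitch exactly.  This is a deliberate special case: the time
lines have intercepts 1.04 and 2.397 rather than the values that would
reproduce the first twitch at `x = 0`, because they are regression fits
over whole decomposed trains; applying them literally to a rest start
would make a single-pulse "tetanus" differ from the unit's own twitch.
The practical consequence is a small discontinuity of the predicted times
as `x → 0⁺`, and the fact that rest-start contractions do not lie on the
prolongation lines (regressions over decomposed trains should therefore
exclude them).

The angle power law exists in two calibrations, `base`
(108.8·ratio^−0.2603, fitted to decomposed training data) and `refined`
(117.2·ratio^−0.3144, refitted to sensitivity-scan optimal angles).  The
default is `base`, the primary published algorithm; the refined law bounds
the angle to [45.70°, 117.2°] over the physiological twitch-to-tetanus
ratio range p ∈ [0.05, 1].  One internal inconsistency of the source data
is worth noting: the contraction-time line's intercept appears both as
1.04 (in the equation, used here) and 1.104 (in a figure caption); both
coefficiencies are overridable through `PredictionConfig`.

**Full prediction.**  The first contraction is the first twitch; for every
later pulse the starting force is the analytic sum of all previously
predicted contractions evaluated at the pulse time (optionally at pulse
time + lead, `lead_offset_in_sampling=True` — the published refinement).
The final trace is the superposition of all modeled twitches on a uniform
grid (default step 0.1 ms), each evaluated only over its own support.  The
trace is exactly the pointwise sum of the train's curves (conservation
identity, tested to 10⁻⁹·F_mftf).

The equations impose no upper force bound.  For strongly fused trains with
small twitch-to-tetanus ratio and `α < 90°` the feedback loop *diverges*
(each contraction raises the starting level of the next without limit);
this is a real property of the literal model, which was calibrated on
moderately fused recordings only.  The package does not hide it — the
synthetic generator instead reproduces the calibration conditions (below).

## Decomposition

`decompose_tetanus` peels a recorded curve apart sequentially.  Fitting
uses bounded least squares (scipy `least_squares`, TRF) on a
reparameterized vector — peak force, lead, half-contraction time, and the
three positive increments between successive time anchors — so every
candidate automatically satisfies the ordering invariant.  Bounds are
[0.2, 8]× the reference twitch's components (decomposed contractions of
slow units can be several-fold larger and longer than the single twitch),
with the lead time's lower bound at 0.

1. *Causal pass*: for contraction *i*, the models of contractions 1…i−1
   are subtracted and a twitch is fitted on `[pulse_i, pulse_{i+1} +
   lead]` (or 3×`T_tw` of the reference for the last one).  A window cut
   short by the next pulse cannot constrain the relaxation shape, so only
   the parameters the data reach are freed (rising phase; then +
   half-relaxation when the window covers it), the rest staying at the
   initial guess — the previous contraction's fit, or the seed twitch.
2. *Refinement passes* (default 1): each contraction is refitted against
   the residual of all *other* current models over its full window, which
   pins down the relaxation parameters.
3. *Optional joint polish* (`polish=True`): one bounded least-squares over
   all contractions simultaneously (dense Jacobian up to 12 contractions,
   sparse support-structured differencing above).  On noiseless
   model-generated trains this recovers the generating parameters
   essentially exactly; it is markedly slower for long trains.

Without a seed twitch the first fit is initialized from the rising phase
after the first pulse (peak position/height, generic shape proportions).
An all-zero residual either raises or returns a zero-amplitude sentinel
(`on_flat`).  Starting force levels are measured as local minima of the
trace on `[pulse, pulse + lead + 2·dt]`; the first is 0 by definition.
When a pulse arrives on a *rising* flank the window minimum sits at the
pulse time rather than at the contraction onset, so minima and
model-internal starting levels agree tightly only for relaxation-phase
arrivals.

Identifiability caveat: in long, strongly overlapping trains the
sequential method reconstructs the *curve* almost perfectly (round-trip
FitCo ≥ 99 on noiseless 41-pulse synthetic tetani) while individual tail
parameters of late contractions can trade off against their neighbours;
exact parameter recovery should only be expected with the joint polish on
resolvable trains.

## Similarity metrics

`FitCo = 100·(1 − sqrt(mean Δ²))` with per-sample differences normalized
to the joint maximum of the two curves (the joint reading makes the
coefficient symmetric in scale and exactly 100 at identity);
`AreaCo = area_ref/area_model` by the trapezoid rule on the shared grid.
Both require identical sampling grids.

## Calibration

The sensitivity scan evaluates the full prediction on the grid "integer
part of the starting angle ± 20° in 0.1° steps" (configurable) against a
reference recording, maximizing `FitCo`; ties within 0.01 percentage
points are broken by `|AreaCo − 1|`, since the published selection rule
names both goals without a combination rule and the fit coefficient is the
primary comparison statistic.  The power-law refit minimizes RMSE in
linear space (not log-log least squares), matching how the law was
originally selected among candidate models; a log-log line supplies the
starting values, and two points are solved exactly.  Time-prolongation
lines are ordinary least squares with Pearson correlations; a constant
response is returned with slope 0 and correlation NaN (flagged
`degenerate`).

## Synthetic data

The generator emulates the statistical structure of the calibration
sample: twitch-to-tetanus ratios normal with mean±SD 0.13±0.05 (S),
0.19±0.06 (FR), 0.28±0.08 (FF), truncated to (0.05, 1); firing rates
uniform in 10–16.6 Hz (S) and 25–40 Hz (fast types); 41-pulse trains with
interpulse intervals i.i.d. uniform within 50–150% of the mean interval.
Twitch times use contraction-time ranges of 30–70 ms (S) and 12–25 ms
(fast) with fixed shape proportions `T_hc = 0.55·T_c`, `T_hr = 2.2·T_c`,
`T_tw = 8·T_c`, lead 1–3 ms, and type-typical amplitude ranges — synthetic
conventions chosen once for plausibility; only their ordering matters to
the algorithms under test.  All randomness flows through one seeded
generator per spec, so every fixture is reproducible.

`make_recording` additionally redraws (unit, rate, train) until the
simulated tetanus peaks at 30–70% of the unit's fused-tetanus force — the
moderate-fusion condition under which the model was calibrated and the
regime where the prediction loop is stable.  Synthetic recordings are the
model's own forward output (plus optional Gaussian noise clipped at zero),
so tests built on them demonstrate internal consistency — round-trip
decomposition, angle recovery, law refits — not agreement with real
muscle: they contain no recording noise floor, no fatigue or potentiation
drift, no baseline offsets and no missed stimuli.

## Problem sizes and numerical choices

The test suite and acceptance checks run on desk-scale problems chosen as
this package's own defaults: ten noiseless 41-pulse tetani (mixed types)
for the decomposition round trip; 20 units per type with 12-pulse trains
for the slow-vs-fast angle separation; 33-point corpora for the power-law
recovery; full ±20° scans on ~11-pulse references for angle recovery.
Optimizer tolerances are 1e-10 (sequential fits) with evaluation budgets
of 400 per free parameter; sampling is 0.1 ms throughout.  Trace grids are
truncated/zero-padded, never resampled, when grids must match.

## Known limitations

* Fatigue, potentiation and nonlinear multi-unit summation are out of
  scope (insufficient data in the source material).
* The coefficients are specific to rat medial gastrocnemius; other muscles
  or species require recalibration of the power law and time lines.
* No upper amplitude constraint is imposed, so strongly fused slow-unit
  predictions can exceed the fused-tetanus force or diverge; callers
  modeling near-fused tetani must impose their own limits.
* Decomposition assumes one contraction per stimulus and a trace covering
  the full train; missed or extra stimuli are not handled.
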