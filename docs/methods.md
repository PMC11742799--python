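# Methods

## The calibration model

`phasensor` treats the OD600 → PHA relation as a static calibration curve
`y = f(x; θ)`: a single, time-independent map from cell density to product
concentration, valid for one organism/medium/process-mode combination.
This is a deliberate simplification — PHA content per unit biomass changes
over a fermentation, and cell morphology and granule load both affect
turbidity — but within one process mode the composite effect is an
approximately stable, monotone relation, which is exactly what a soft
sensor needs. The assumption visibly breaks when the process mode changes;
the online-update machinery exists for that case.

Thirteen candidate structures are provided (ids 1–13): power law
`a·x^b`, logarithmic `a + b·log x` (natural log; the base is absorbed by
`b`), hyperbolic saturation `a·x/(b+x)`, saturating exponential
`a(1−e^{−bx})`, geometric `a − b·c^x`, rational `(a+bx)/(1+cx)`,
saturating-exponential power `a(1−e^{−bx})^c`, four-parameter log-logistic
`a(1−[1+(x/c)^d]^{−b})`, Weibull-type `a(1−e^{−(b(x−c))^d})`, and
polynomials of degree 1–4. The log-logistic is occasionally printed with
unbalanced brackets in the literature; the form above is the only
well-formed, sigmoidal reading and is what this package implements. Each
structure carries a domain guard (e.g. `x > 0` for the logarithm, `c > 0`
for a real power `c^x`, non-negative bases for fractional powers) and an
analytic derivative `df/dx` used for error propagation.

## Fitting

Parameters minimise the weighted residual sum of squares. The optimizer is
Nelder–Mead simplex — derivative-free, robust to the mild
ill-conditioning of the saturating structures, and faithful to how such
calibrations are fitted in practice — with absolute x- and f-tolerances of
1e−8 and an iteration cap of 400·M per start. Because the simplex is a
local method and several structures (5, 8, 9) have genuinely non-convex
objectives, every fit is multi-start: one deterministic heuristic guess
(closed-form least squares for the polynomials, log-log / semi-log
regressions for the power and logarithmic laws, `1.1·max(y)` plateau plus
scale guesses for the saturating family) plus 10 perturbations obtained by
multiplying each nonzero component by a log-uniform factor in [0.2, 5]
(seeded; zero components get small additive jitter). The best feasible
local optimum is polished by one further simplex run from that point.
Guard violations make the objective +∞ rather than raising, so infeasible
corners of parameter space are simply never accepted. Fits are fully
deterministic given (data, options, seed).

Fitting requires N ≥ M + 2 points. A structure whose every start is
infeasible is recorded with RSS = ∞ and excluded from ranking.

## Selection

Candidates are compared by AICc and R². Two conventions deserve emphasis:

* **Base-10 logarithm.** `AICc = N·log₁₀(RSS/N) + 2MN/(N−M−1)`. The
  published selection tables bundled in `phasensor.reference` are
  reproduced, cell for cell, by this base-10 form with N = 24 (maximum
  reconstruction error 0.036, within the rounding of the three-decimal RSS
  values); the natural-log variant reproduces none of them. Absolute AICc
  values from this package are therefore smaller in magnitude than
  natural-log AICc by a factor ln 10; differences and rankings are what
  matter, and those are unaffected by any monotone rescaling of the
  first term's base only within a fixed N, so comparisons must always use
  one convention consistently.
* **Unit-weight metrics.** RSS, AICc and R² are always computed with unit
  weights, even when the fit minimised a weighted objective: N is a count
  of real data points, and up-weighting recent measurements expresses
  trust, not extra data.

The *chosen* model applies a parsimony tie-break: candidates within
ΔAICc ≤ 2 of the minimum are considered statistically indistinguishable,
and the one with fewest parameters (then lowest id) is taken. This mirrors
the practice of preferring a 2-parameter power law over a near-tied
quartic. An RSS of exactly zero (interpolation) yields AICc = −∞ with a
warning rather than an error, so noiseless oracle data rank sensibly.

## Estimation and uncertainty

Prediction is plain evaluation of the fitted curve. The reported
uncertainty is first-order propagation of the OD replicate SD only:
`σ_PHA = |f′(OD)|·σ_OD`, exact for linear maps and homogeneous of degree 1
in `σ_OD`. Parameter covariance is *not* included: the simplex fit
produces no covariance estimate, and the bundled reference calibrations
ship without one, so including it would require bootstrap machinery that
is out of scope. The band therefore understates total uncertainty,
particularly under extrapolation. OD values outside the calibration range
are estimated anyway — applying a batch-trained curve to a continuous
process that grows further is the method's central use case — but flagged
`extrapolated` in the output.

Cross-validation scores a fitted curve on labeled datasets by MAE (g/L),
robust to the occasional outlying reference measurement.

## Online update

An update at trigger time `t` (typically a known process-phase change)
extends the original training set with all in-process samples whose
reference measurement is available, refits, and optionally re-selects the
structure. Two policy constants matter:

* `weight_new = 5`: each new point's squared residual is multiplied by 5
  in the objective (prior points keep weight 1 — only the new data are
  emphasised). Integer weights are exactly equivalent to physically
  replicating rows, a tested invariant.
* `lag_h = 2`: a sample drawn at time `s` becomes usable at `s + lag_h`
  (the HPLC turnaround); the update is applied at the first sampling time
  ≥ `t + lag_h`. With the bundled test-process sampling grid this maps
  triggers at 12 h and 40 h to application at 14 h and 43 h with 9 and 20
  usable new points (extended sets of 33 and 44 from a 24-point prior).

## The synthetic generator

Real trajectories exist only as figures, so the generator emulates their
statistical shape:

* **OD:** logistic growth `od(t) = od_max/(1 + ((od_max−od0)/od0)e^{−rt})`
  — the simplest monotone sigmoid with the right endpoints. Defaults:
  `od0 = 0.4` (standard inoculation target), `od_max = 60` (PHB batch; 35
  for the PHBV fed-batch), `r = 0.25 h⁻¹` (a realistic *C. necator*
  growth rate placing the inflection near 20 h), 24 samples over 45 h
  (sampling every ~2 h), in triplicate.
* **Noise:** multiplicative Gaussian on each OD replicate
  (`od_rel_noise_sd = 0.02`, i.e. 2% photometric error) and additive
  Gaussian on PHA (`pha_noise_sd = 0.1 g/L`, the order of HPLC replicate
  scatter), truncated at zero to keep concentrations physical.
* **Mismatch:** an optional constant multiplicative bias on PHA after a
  shift time. The PHB-like test pair uses bias 0.85 after 12 h, emulating
  a continuous phase in which real PHA falls below the batch-trained
  curve so the incumbent model overestimates.

What the generator does *not* emulate: substrate dynamics, cell-morphology
effects on turbidity, autocorrelated drift, outliers, or non-constant HPLC
variance. Passing tests on synthetic data therefore demonstrate that the
*workflow* (fit → select → estimate → update) behaves correctly under its
own statistical assumptions, not that any particular curve will transfer
to a new organism or medium.

## Numerical choices and degenerate inputs

* Tolerances: simplex `xatol = fatol = 1e−8`; noiseless recovery of the
  bundled curves reaches RSS ≲ 1e−18.
* Ties in selection: ΔAICc ≤ 2 window, fewest parameters, lowest id.
* `R²` is undefined (raises) when all PHA values are identical; AICc
  requires `N > M + 1` and raises otherwise.
* Derivatives at guard boundaries (e.g. `x = 0` for `0 < b < 1` power
  laws) are reported as the one-sided limit (∞) and rejected as
  non-finite rather than silently clipped.
* Problem sizes in the test and acceptance runs — 20 seeds for the
  stochastic recovery and update studies, 50 random OLS datasets, 100
  random derivative triples — were chosen to make the binomial acceptance
  thresholds (≥16/20, ≥18/20) meaningful while keeping each study a
  single-CPU job of seconds to tens of seconds.

## Known limitations

* The uncertainty band excludes parameter covariance (see above).
* The catalog is fixed at the 13 structures; transferring the workflow to
  another process may require different candidate families, which would
  be added to the catalog rather than configured.
* Model selection on strongly correlated saturating structures (7 vs 8
  vs 13) is noise-sensitive near the tie window; the parsimony tie-break
  makes the choice deterministic but not necessarily "true".
* No outlier rejection is applied to OD series; a single bad OD reading
  propagates directly into the PHA estimate.
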