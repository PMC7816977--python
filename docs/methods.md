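# Methods

This note documents the models implemented in `dissolvekit`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## Dissolution statistics

**Similarity factor f2.** For a reference profile R and test profile T on a
shared grid of n post-zero sampling times,

    f2 = 50 · log10( 100 · [1 + (1/n)·Σ (R_t − T_t)²]^(−1/2) ).

The exponent is −0.5: only that sign makes the score *decrease* as profiles
diverge, consistent with the universal reading that f2 < 50 flags a
significant difference (the formula occasionally appears in print with a
spurious +0.5). Identical profiles give exactly 100; an average 10-point
gap gives 100 − 25·log10(101) ≈ 49.89, the classic "10% difference ⇒ f2 ≈
50" identity. The t = 0 point is excluded by default (both curves are zero
there by construction, which only inflates the score); `include_t0=True`
restores it. The regulatory "at most one point above 85% dissolved"
truncation is available via `fda_truncation=True` but off by default, since
f2 is here a descriptive profile statistic computed on full curves.

**Dissolution efficiency.** DE%(t) is the trapezoidal area under the
cumulative curve over [0, t] divided by the area of instantaneous complete
dissolution (100% · t). Profiles lacking a t = 0 sample are anchored at
(0, 0) — the dose is undissolved at test start. The endpoint is linearly
interpolated when unsampled; extrapolation beyond the data is refused.

**Mean dissolution time.** MDT = Σ t*_j ΔM_j / Σ ΔM_j with t*_j the
interval midpoint and ΔM_j the percent dissolved in interval j. For a
first-order curve sampled finely over ≥ 6 half-lives this converges to 1/k
(continuous limit ∫t dM / ∫dM). Noisy cumulative data can produce negative
increments; the literal formula uses them as-is (with a warning), and a
running-maximum `monotonize` pre-pass is available when a strictly
non-decreasing curve is wanted.

**Reporting convention.** Fold changes, bioavailability percentages and
validation ratios are half-even rounded to 2 decimals; raw values are
available via `rounded=False`.

## Release kinetics

Zero-order and Higuchi fits are intercept-free least squares in the
original percent-dissolved space — these are the standard one-parameter
release laws, and the intercept-free convention is what allows grossly
mis-specified models to score strongly negative R², a useful rejection
signal. The first-order model is linear in log10(percent remaining) with a
free intercept (log10 C₀), reported as K = −slope·ln 10 in min⁻¹.

Numerical choices:

* Points with ≤ 0.5% remaining are excluded from the first-order fit (a
  profile that reaches or exceeds 100% dissolved makes the log argument
  non-positive; some exclusion rule is logically required) with a warning.
* The log-space regression is variance-weighted with weights proportional
  to percent remaining. By the delta method, sd(log10 C) ≈ sd(C)/(C·ln 10),
  so unweighted log-least-squares lets near-complete points — where 1%
  assay noise is enormous relative to the remaining fraction — dominate and
  bias K. The weighting is the Gauss–Newton linearization of the
  observation-space fit and is exact on noiseless data.
* R² for **all three** models is computed in the original percent-dissolved
  space against the mean-centered total sum of squares, so models compete
  on one scale; a linearized-space R² is available via
  `r2_space="linearized"` (the two can differ substantially for the
  first-order model, which is why cross-model comparisons use observation
  space).
* Mechanism selection is argmax R² with the deterministic tie-break
  zero → first → Higuchi. No information criteria are used; the model set
  is deliberately closed to these three laws.

## Design of experiments

The design crosses drug:polymer ratio (polymer parts 1, 2, 4 — treated as a
*numeric* factor so a quadratic term is estimable; a categorical treatment
would forfeit curvature) with polymer type (4 levels, sum-to-zero contrasts
so the intercept is the grand mean). Model orders: linear (intercept, A,
3 contrasts), 2FI (+ A×contrast products), quadratic (+ A²). The model
matrix must be full rank; aliased columns are reported by name.

Fit statistics follow response-surface conventions: ANOVA partitions the
residual into lack-of-fit and pure error using replicate groups (runs with
identical settings — the packaged 18-run table has six duplicated settings,
giving 6 pure-error df); PRESS uses the hat-matrix identity
Σ[e_i/(1−h_ii)]², verified in tests against explicit leave-one-out refits;
predicted R² = 1 − PRESS/SStot; adequate precision is the signal-to-noise
(max ŷ − min ŷ)/√(p·MSE/n), with values > 4 conventionally indicating a
usable surface.

Desirability optimization (Derringer–Suich) maps each predicted response
through a linear ramp over the observed response range (maximize:
(ŷ−L)/(T−L); minimize mirrored; clipped to [0, 1]; importance weights fixed
at 1), combines by geometric mean, and exhaustively scores the 12 candidate
factor combinations. On the packaged measured design the optimum is the
PEG 8000, 1:4 drug:polymer setting regardless of response ordering.

The packaged design is the literal printed 18-run table; no I-optimal
candidate search is performed (the original design was generated by
commercial software, and regenerating it is out of scope). Note that the
published fit-statistics table for this design could not be reconciled with
the raw runs under any standard coding (e.g. R² ≈ 0.9999 for a linear fit
of a visibly non-monotone response); this package reports what OLS on the
printed runs actually yields, and its tests assert structural invariants
(R² ≥ adjusted ≥ predicted, PRESS ≡ LOO) plus the desirability optimum,
which does reproduce.

## XRD relative crystallinity

DRC = I_sample/I_reference at a characteristic angle (default window ±0.5°
around the nominal angle; only the angle itself is usually published). Peak
height is the maximum of intensity minus a straight baseline through the
window's endpoint samples, floored at 0 — raw height ratios are not
comparable across instruments with different backgrounds, hence baseline
correction by default and a `baseline="none"` mode for parity with
uncorrected published ratios. DRC is scale-invariant and reciprocal
(DRC(a,b)·DRC(b,a) = 1).

## Oral PBPK model

A deliberately transparent stand-in for commercial mechanistic-absorption
software, whose internals are proprietary: absolute plasma predictions are
therefore **not** claimed — the model is accepted on structural properties
(mass balance, analytic limits, monotonicity, seed determinism) and used
for within-model contrasts (formulation and population effects).

Structure: stomach (solid + dissolved) → 7 intestinal transit compartments
(solid + dissolved each) → colon. First-order processes throughout:

* dissolution at k_d (from the formulation's in-vitro first-order fit,
  applied minute-for-minute in vivo, or given directly),
* gastric emptying k_ge = ln2/0.25 h⁻¹ (fasted half-life 0.25 h),
* transit k_t = 7/3.32 h⁻¹ per compartment (total small-intestinal transit
  3.32 h) — standard transit-model literature values,
* absorption of dissolved intestinal drug at k_a (default 1.2 h⁻¹, a
  moderate-permeability acid), surviving pre-systemic extraction with
  F = 0.45 (midpoint of the compound's reported 35–56% oral
  bioavailability range),
* zero colonic absorption: material exiting the last transit compartment
  is lost (conservative for a dissolution-limited BCS II acid),
* one-compartment disposition: V = Vss·body weight (0.23 L/kg), CL =
  1.5 L/h.

MW, pKa, logP, blood/plasma ratio and fu are carried in `CompoundParams`
for provenance and reporting but do not enter these equations; they would
parameterize a fuller mechanistic model. The 150 mL of co-administered
water in the simulated dosing scenario is likewise metadata, not a model
state.

Integration uses LSODA with rtol 1e−8 on a 0.05 h output grid over 0–24 h.
Three bookkeeping states (cumulative eliminated, colon arrival,
pre-systemic loss) close the mass balance, so conservation is checkable at
every grid time; tests require max error < 0.1% of dose and observe
~1e−12%. In the instant-dissolution/absorption limit the curve matches the
closed-form one-compartment oral bolus within 0.1%, and for
complete-absorption runs trapezoid AUC₀₋∞ (log-linear tail C_last/k_e)
equals F·D/CL within 0.5%.

Virtual populations: 10 trials × 10 subjects by default, dose 50 mg.
Subject deviates are mean-1 log-normal (CV 30% on CL and k_a, 20% on V);
body weight ~ Normal(81, 10) kg for middle-aged adults, Normal(75, 10) kg
for geriatrics, whose clearance is additionally scaled by 0.75 — reflecting
reduced glomerular filtration, liver mass and hepatic perfusion with age —
which makes geriatric exposure strictly exceed adult exposure at identical
seeds. Per-subject RNG streams derive from (seed, trial, subject), so any
subject is reproducible in isolation. Summaries report mean ± SD Cmax and
AUC₀₋₂₄ and median Tmax.

## Synthetic generators

Every generator is a pure function of its spec including the seed.
Dissolution profiles follow first-order, Weibull, zero-order or Higuchi
ideal curves on a configurable grid (default 0–60 min at a typical paddle
schedule), with i.i.d. Gaussian noise floored at 0% but not capped at 100%
(real assay means do exceed 100%). DoE datasets reproduce the 18-run
replicate layout with responses from known coded coefficients. XRD patterns
are Gaussians on a flat baseline, emulating a crystalline drug's strong
low-angle reflections (4°, 10.4°, 17.5°).

What passing tests on synthetic data show — and what they do not: the
generators validate *estimator correctness* (parameter recovery, model
selection, statistic oracles) under clean noise assumptions. They do not
emulate correlated replicate error, cascade/filtering artifacts in
dissolution sampling, instrument drift in XRD, or any in-vivo variability
structure beyond log-normal scaling; conclusions about real data rest on
the methods being standard, not on these simulations.

## Problem sizes

Default verification sizes were chosen to make the statistical checks
well-powered while remaining quick: 1,000 random profiles against a
10⁴-substep rectangle-sum oracle for DE/MDT; 100 seeded noisy profiles per
kinetic model for recovery; 20 seeded datasets for the PRESS/LOO identity;
100-subject populations per PBPK arm.

## Known limitations

* f2 is a point estimate; no bootstrap confidence intervals or multivariate
  distance methods.
* Kinetic model set excludes Korsmeyer–Peppas/Weibull fitting (the Weibull
  appears only as a generator shape).
* The DoE stage fits and optimizes the printed design; it does not
  construct optimal designs.
* The PBPK model omits enterohepatic recycling, metabolite kinetics, food
  effects, pH-dependent solubility and colonic absorption; its absolute
  exposure predictions are intentionally not calibrated to any clinical
  dataset, and between-arm significance testing is out of scope.
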