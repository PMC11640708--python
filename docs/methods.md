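# Methods

## Synthetic cohort generator

The generator emulates a mid-life cardiovascular screening cohort with the
classic tabular schema: age (days), height (cm), weight (kg), systolic and
diastolic pressure (mmHg), cholesterol and glucose grades (1–3), binary
smoking/alcohol/activity flags, gender (1/2) and a binary cardiovascular
outcome.  Default marginals (age ≈ 53 y ± 6.8 y, ap_hi 126.6 ± 16 mmHg,
smoking prevalence 8.8%, …) approximate published summaries of screening
populations of this schema; they are configuration, not constants.

Mixed-type correlations are induced with a **Gaussian copula**.  A latent
multivariate normal vector is sampled and each coordinate is pushed through
its marginal transform: linear for continuous columns, quantile thresholds
for binary and ordinal ones.  Because thresholding attenuates correlation,
the latent correlation for each requested pair is calibrated by inverting
the latent→observed Pearson map: in closed form for
continuous–discrete pairs (cov(X, 1{Z>c}) = ρ·φ(c)) and by Brent root
finding on the bivariate normal orthant probability for discrete–discrete
pairs.  The assembled matrix is projected to the nearest positive
semi-definite correlation matrix (eigenvalue clipping) before sampling.
Planted pairwise r values are recovered within ±0.05 at n = 10⁴.

The outcome column is thresholded **per gender group** at Φ⁻¹(1 − rate_g),
so group-conditional outcome rates are planted exactly (up to binomial
noise) while the outcome's latent correlations survive.  Default cohort
size is 10,000; the headline planted structure is age–outcome r = 0.24,
weight–outcome r = 0.18, gender–smoking r = 0.34, glucose–cholesterol
r = 0.45, smoking–outcome r = −0.02, plus ap_hi–ap_lo r = 0.70.

Choices made where the design was open:

- diastolic pressure is clipped to at least 5 mmHg below systolic rather
  than generated jointly; the clip slightly distorts the ap_lo marginal in
  the upper tail but guarantees no inversions;
- pack-years for smokers are built from a log-normal cigarettes/day
  (median 15) and a uniform fraction (0.3–1.0) of the years since age 18;
  non-smokers get 0.  Pack-year bins are half-open: [0,10), [10,20), [20,∞);
- bias factors are drawn i.i.d. normal with configurable mean (default
  −0.10, i.e. a 10% transmission reduction) and sd 0.02 — the normal form
  is a declared modelling choice, not an empirical claim;
- mask pairs are rasterised equal-radius disks; the predicted disk is
  translated, with a coarse-to-fine search on the translation, until the
  rasterised Dice hits the target within ±0.05.

What the generator does **not** emulate: measurement error structure,
missing data, real marginal shapes (age is truncated-normal-ish in real
screening data, not normal), higher-order dependence beyond pairwise
Pearson, or cohort selection effects.  Passing tests therefore demonstrate
correctness of the estimators and operators under known ground truth, not
performance claims about any real population.

## Fairness metrics

All difference metrics are signed unprivileged − privileged; ratios are
unprivileged / privileged.  Group rates come from exact confusion counts;
a group with no positive (or no negative) true labels raises an
undefined-rate error naming the group rather than returning a silent 0 —
degenerate inputs should fail loudly, because silently degenerate fairness
values (e.g. a disparate impact of exactly 0) mask broken pipelines.

The Theil index is the generalised entropy index with α = 1 applied to
per-subject benefits bᵢ = ŷᵢ − yᵢ + 1 (0 for false negatives, 1 for
correct predictions, 2 for false positives), the convention of the
standard fairness toolkits; 0·ln 0 is taken as 0 and an all-zero benefit
vector is an error.

## Mitigation operators

**Reweighting** uses the baseline model's probability of each subject's
observed label, clipped to [10⁻³, 1] so that weights are bounded by 1000.

**Balanced probability adjustment (BPA)** multiplies scores by
1 + α·ΔTPR + β·ΔFPR and re-thresholds (strict p̂ > θ, θ default 0.5).  The
literal form applies one global multiplier ≥ 1, which moves both groups'
rates in the same direction and cannot close a gap on its own; it is kept,
exactly as specified, under `mode="literal"`.  The pipeline default
`mode="directed"` assigns the +α·ΔTPR term to the group with the *lower*
TPR (raising its scores raises its TPR toward the other group's) and the
−β·ΔFPR term to the group with the *higher* FPR; a group holding neither
role receives no term.  Closing each gap from its disadvantaged side only
is deliberately conservative: symmetric two-sided pushes double the step
size and empirically overshoot past parity at moderate α, β.  Defaults
α = β = 0.5 keep the multiplier within [1 − ΔFPR/2, 1 + ΔTPR/2].

**Equalised-odds scaling** multiplies non-target-group scores by k.  The
selection of k is a grid search (default 0.5–2.0, step 0.1) minimising
|ΔTPR| + |ΔFPR| after re-thresholding, with ties broken toward k = 1
(least intervention).  Because k = 1 (the identity) is in the default
grid, the selected k can never be worse than doing nothing.

**Counterfactual search** discretises the caller's feature box and
enumerates it exhaustively, returning the feasible grid point nearest in
Euclidean distance (first in C order on ties) or an explicit not-found
result.  Exhaustive search is exact at desk scale; a guard rejects grids
above 2×10⁶ points.

## Epidemic models

The SIR equations are implemented in both the density-dependent (−βSI)
and frequency-dependent (−βSI/N) forms; the density-dependent form is the
default because it is the one consistent with the reference trajectories
(at the initial state (4,4,1,1), dS/dt must be −0.4, not −0.04, to reach
S = 3.58 by t = 1.02).  The two agree exactly when N = 1 (tested).  The
SCIR variants add a compartment C between S and I; in the carrier variant
transmission is driven by I (force −βSI), again fixed by reproducing the
reference state at t = 1.02.

Integration defaults to adaptive Dormand–Prince 5(4) (`solve_ivp`,
rtol 10⁻⁸, atol 10⁻¹⁰, dense output); population conservation is asserted
at every output time.  Halving tolerances does not change any value at
reporting precision (2 dp / 3 sf) — except one quantity:

**The susceptible tail.**  In the high-rate carrier configuration
(β=0.5, δ=0.2, γ=0.15) the susceptible pool collapses to ~10⁻¹² by t ≈ 50,
four orders of magnitude *below* the absolute tolerance.  At that
magnitude the computed digits are solver truncation noise: the converged
value (verified with DOP853 at rtol 10⁻¹³ and with an exact log-S
reformulation) is S(50) = 3.99×10⁻¹³, while classic default-tolerance
LSODA — the historical `odeint` setup ubiquitous in epidemiological
scripts — yields ≈ 2.5×10⁻¹², and the exact digits vary with the output
grid and library build.  Both integration modes are exposed:
`method="RK45"` (default) and `method="legacy-lsoda"` (LSODA at its
classic default tolerances on a uniform grid of pitch 0.02, fine enough to
put every reported time on-grid).  The acceptance script uses the legacy
mode, which reproduces the reference tail values to within ~1.5%; no
integrator reproduces their third significant figure, and we do not tune
toward it.  Every quantity of physical size (S and C at t=1.02, I and R at
t=50) is identical across modes at reporting precision.

"Total cases" for the recovery-rate summary is not uniquely defined for a
model seeded with infected and carrier individuals; the default counts
I(0) plus the integrated flux into I (trapezoid on the trajectory), with
"initial carriers included" selectable.  Total recoveries are
R(T) − R(0), the exact integral of γI.  The recovery *rate* is the ratio
of the two and can exceed 1 when recoveries drain initial carriers that
are not counted as cases — it is a summary ratio, not the per-capita γ.

## Audit pipeline

The train/test split (default 80/20) is stratified jointly on
(outcome, group) so that all four group-rate denominators stay populated
in both splits.  The baseline classifier is an L2-regularised logistic
fit on standardised features (scikit-learn); any calibrated probabilistic
classifier satisfies the contract.  Fairness metrics are computed on the
test split.  No multiple-testing correction is applied: raw metric values
are reported with seeds and config hashes logged, leaving adjustment to
the consumer.  All randomness (cohort, split, fit) derives from config
seeds; identical configs produce byte-identical reports.

## Problem sizes used in the test suite

Planted-rate and correlation recovery are tested at n = 10⁴ with binomial
tolerances (±0.02 on rates, ±0.05 on r).  Planted-disparity properties
(parity-gap recovery within 3.3 standard errors, mitigation
non-degradation) run over 20 seeded cohorts of 10⁴ subjects with a planted
outcome-rate gap of 0.16.  Metric oracle equivalence uses 1000 random
instances of n ≤ 50 against pure-loop counting; mask identities use 1000
random 16×16 pairs; conservation uses 100 random SCIR draws over t ∈
[0, 25].

## Known limitations

- The copula calibration for the outcome column uses the pooled outcome
  rate; with very unequal group rates the planted outcome correlations are
  recovered slightly attenuated (still within the ±0.05 band at defaults).
- Directed BPA is guaranteed non-degrading only in the regime it is
  designed for — gaps that are genuinely above measurement noise; on
  near-null gaps (≲ 0.03) the re-measured gap can wobble within noise.
- The carrier-variant SCIR susceptible tail below ~10⁻¹⁰ individuals is
  numerically meaningless in any fixed-tolerance integration (see above).
- No stochastic (Gillespie) epidemic simulation and no rate fitting to
  data; the models are deterministic ODEs with user-supplied rates.
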