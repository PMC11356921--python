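# Methods

## Scope and design

The package implements a four-step cost-of-illness (COI) analysis of a
dietary blood-pressure intervention as a seeded, testable pipeline:

1. choose an intake success rate r (the share of the eligible
   hypertensive population adopting the regimen);
2. model the intervention's effect on systolic and diastolic pressure
   as per-person uniform draws spanning published meta-analytic 95%
   CIs — SBP U(2.24, 4.15) mm Hg, DBP U(1.94, 3.27) mm Hg;
3. estimate the reduction in hypertension prevalence on person-level
   survey microdata;
4. price the remaining hypertensive population with an age-band table
   of annual per-capita attributable costs (2020 CAD) and report the
   saving relative to baseline.

Steps 2–4 run inside a Monte Carlo loop (default 1000 iterations per
rate); step 1 is a partial sensitivity analysis over
r ∈ {5, 10, 25, 50}%.  The real analysis input is a restricted national
health-measures clinical file; this package substitutes a synthetic
population generator with the same statistical skeleton, so every
downstream stage is exercised end to end without any data access.

## Hypertension definition and weighted estimators

A record is hypertensive iff SBP ≥ 140 mm Hg, DBP ≥ 90 mm Hg, or
anti-hypertensive medication is self-reported.  Cut-points are
inclusive (≥): where prose conventions ("over 140") and the formulaic
definition disagree, the formula wins.

Prevalence and mean BP are survey-weighted.  Confidence intervals use
a normal approximation at the Kish effective sample size
n_eff = (Σw)² / Σw².  Survey agencies conventionally use bootstrap
replicate weights, which are unavailable for synthetic data; intervals
are therefore labelled `normal_effective_n` and are not claimed to
reproduce design-based CIs.  Records with any missing or invalid field
are rejected at read time (fail-fast); no imputation is attempted.

## The simulation engine

**Weight expansion.**  The hypertensive set H is expanded into the
population-scale H′.  `replicate` mode repeats each record round(w)
times (round half away from zero) — the literal construction, exact for
integer weights.  The default `weighted` mode keeps one row per record
with real multiplicity w and an integer `units = max(1, round(w))`
column; adoption is then binomial thinning (`Binomial(units, r)/units`
of the multiplicity), equal in expectation to per-copy sampling and
cheap at national scale (no 5.8-million-row frame per iteration).  In
weighted mode a single medication/effect draw per record stands in for
its copies' i.i.d. draws — identical in expectation, slightly wider
per-iteration dispersion; a test verifies both modes agree on mean
savings within Monte Carlo error.

**Medication back-adjustment.**  Medicated respondents' measured BP is
raised by U(8.8, 9.3) / U(5.4, 5.7) mm Hg (SBP/DBP) before eligibility
is assessed, because medicated-but-controlled respondents would
otherwise sit below the cut-points with nothing to convert from.
Unmedicated records keep their measured BP bit-exactly.

**Eligibility and adoption.**  K is the subset of H′ with adjusted
SBP ≥ 140 or adjusted DBP ≥ 90.  Medicated records still below both
cut-points after adjustment remain hypertensive (and costed) but are
not eligible.  |F| = round(r·n_K) in replicate mode; thinning gives the
same marginal rate in weighted mode.

**Reclassification.**  An adopter exits the hypertensive state iff
both treated pressures fall strictly below their cut-points — the
logical negation of the hypertension rule.  Medication status is
deliberately not consulted at this step, following the formulaic
post-treatment definition: a medicated adopter whose treated BP
normalises stops bearing attributable costs even though they still
take medication.  This is arguably generous — the baseline definition
would keep them hypertensive — and is the main structural open
question of the design; it is logged and confined to `reclassify`.

**Costing.**  Annual per-capita attributable costs by age band
(2020 CAD): 18–44: 2095.73; 45–54: 2305.30; 55–64: 2514.87; 65–74:
2934.02.  The published table has no 75+ row although 75+ has the
highest prevalence; the default imputes the 65–74 value for 75+
(conservative, as attributable costs generally rise with age), logs
the assumption prominently, and is overridable via the cost-table CSV.
The table derives from provincial administrative data scaled to the
national level using a 4.27% provincial per-capita spending excess
(7014.33 vs 6727.38 CAD); `percent_excess` reproduces that arithmetic.
Costs are constant 2020 CAD with no discounting or inflation
adjustment, and identical across sexes within a band.

**Savings identity.**  savings = Σ converted·C is computed directly
and adjusted_cost = total − savings, so conservation holds to
floating-point exactness.

## Monte Carlo driver

Effect-size uncertainty is redrawn **per person per iteration** (the
per-person indexing of the effect draws dictates this; drawing one
population-level effect per iteration — common in COI practice — would
understate within-iteration heterogeneity and change the conversion
probability nonlinearly).  Per-(rate, iteration) RNG substreams derive
from the master seed and the rate *value*, so reordering or subsetting
the rate grid never changes a per-rate result.  Savings are summarised
by mean, SD and the 2.5/97.5 percentile interval of the iteration
distribution — the standard probabilistic-sensitivity-analysis
presentation; the interval method for the original table is unstated,
so ours is labelled a Monte Carlo percentile interval.

**Validation oracle.**  With degenerate (point-mass) medication
effects, adjusted BP is deterministic and expected savings have the
closed form Σ_{l∈K} r · P_S(l) · P_D(l) · C_l, where
P_S = clamp((high_S − (SBP_adj − 140)) / (high_S − low_S), 0, 1) and
analogously P_D.  Expected savings are exactly linear in r.  Tests
check the Monte Carlo mean against this oracle within 3 standard
errors, linearity in r, null-treatment invariance (zero-width effect at
zero ⇒ savings ≡ 0), and saturation (r = 1 with an overwhelming effect
⇒ savings = cost of K exactly).

## Synthetic population generator

The generator emulates the structure the analysis needs, not any real
respondent data:

* **Strata** — five age bands (the four cost bands plus 75+) × sex,
  with shares approximating the national adult distribution
  (0.435 / 0.160 / 0.175 / 0.125 / 0.105 across bands, ~49/51 M/F).
* **Blood pressure** — per stratum, SBP is truncated normal on
  [60, 260] mm Hg; DBP is its conditional normal (default correlation
  0.5) truncated to [30, min(160, SBP)].  The published summaries give
  only marginal means, so the joint dependence is a model choice and
  configurable — eligibility depends on the joint upper tail, so the
  correlation materially affects savings magnitude.
* **Medication** — stratum-level Bernoulli rising with age (2% young
  adults to 47% at 75+), independent of BP by default; an optional
  logistic link on the SBP z-score concentrates medication at higher
  pressures.  Under the default, roughly half of medicated individuals
  sit below the cut-points, so the medicated-but-controlled group the
  back-adjustment exists for arises naturally.
* **Weights** — i.i.d. lognormal with CV 0.5, rescaled to sum exactly
  to `weight_total` (default 29 million, the order of the national
  adult population; a plumbing default, not a published figure).

Default stratum means were chosen once so an uncalibrated draw lands
near the published anchors (overall mean SBP/DBP ≈ 113.3/72.3 mm Hg,
prevalence ≈ 20.02%, 75+ ≈ 62%).  Sampling is inverse-CDF throughout
(no rejection loops), which makes generated pressures monotone in the
stratum means at a fixed seed — the property calibration exploits.

**Calibration.**  `calibrate_to_targets` fits prevalence targets by
bisection on a one-dimensional adjustment per target: stratum SBP means
shift by δ, DBP means by 0.6·δ, and for downward shifts medication
probabilities are damped by exp(δ/10) (prevalence cannot fall below the
medication floor by mean shifts alone).  Band targets are fitted first
on their own strata, then the overall target on the remaining strata.
The objective is evaluated *analytically* — `expected_prevalence`
integrates the truncated-normal model by 128-node Gauss–Legendre
quadrature — so calibration is deterministic, noise-free and runs in
milliseconds; a fresh sampled draw is reported alongside for sanity.
Targets beyond a ±40 mm Hg shift raise a diagnostic naming the
worst-missed target.

**What passing tests do and do not show.**  The generator reproduces
marginal means, age/sex gradients and calibrated prevalences, but not
the true joint (SBP, DBP) distribution near the 140/90 corner, the
share of medicated-but-controlled respondents, survey design effects
(clustering, replicate weights), or any covariance between weights and
health status.  Savings magnitudes on synthetic data are therefore
order-of-magnitude checks of the pipeline, not re-estimates of the
published totals, which were computed on the restricted clinical file.

## Numerical and operational choices

* Problem sizes: tests and the acceptance script use populations of
  20,000–50,000 respondents and 200–2000 iterations per rate — large
  enough that calibrated prevalences resolve to a few tenths of a
  percentage point and Monte Carlo SEs are ~1% of the mean.
* Boundary ties: all threshold comparisons are inclusive (≥) for
  disease state and strict (<) for conversion, the exact negation.
* Degenerate uniform effects are point masses; their tail probability
  is the indicator d < low.  Effect draws consume one uniform per
  person regardless of degeneracy, keeping RNG streams aligned.
* CSV dialect pinned (comma, "." decimal, UTF-8, Unix newlines);
  money carried as float CAD, rounded to the cent only in reports,
  shown in CAD and CAD millions.
* Every stochastic operation takes an explicit seed or Generator; no
  global RNG state is read anywhere.

## Known limitations

* Medication-class heterogeneity is out of scope — one overall
  back-adjustment distribution applies to all medicated respondents.
* No indirect costs, QALY/DALY weighting, cholesterol co-benefits,
  discounting, multi-year projection, or longevity offsets.
* The 75+ cost band is imputed (see above).
* Replicate mode's weight rounding biases totals when weights are far
  from integers; weighted mode is exact in expectation and is the
  default.
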