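# Methods

## The problem

Gestational weight gain (GWG) is usually reported as the difference between
a weight measured at delivery and a self-reported pre-pregnancy weight.
That definition confounds true weight gain with gestational age (GA) at
delivery (a woman delivering at 38 weeks has simply had less time to gain),
and it discards every woman without a delivery measurement.  This package
implements a model-based standardization: all observed weights — the
self-reported pre-pregnancy weight at GA 0 and the clinic/home/delivery
measurements — are fitted jointly with a hierarchical growth model, and GWG
is read off the fitted subject curves at fixed gestational ages (12+0,
28+0 and 40+0 weeks, i.e. 84, 196 and 280 days), so every participant
contributes and every estimate refers to the same pregnancy horizon.

## Model

Weight of subject *i* (arm *g(i)*) at GA *t* days:

    w_ij = (β₀ + b₀ᵢ) + (β₁g + b₁ᵢ)·min(t_ij, τ_g)
                       + (β₂g + b₂ᵢ)·max(0, t_ij − τ_g) + ε_ij

* β₀ — common intercept (kg).  The arms are randomized, so baseline weight
  cannot differ by arm; forcing a common intercept encodes that.
* β₁g, β₂g — pre- and post-change slopes per arm (kg/day).  β₂g is the slope
  itself, not an increment.
* τ_g — arm-level change-point (days), prior Uniform(50, 250).  Subjects
  inherit their arm's change-point; the data carry too little per-subject
  curvature information to support subject-level change-points.
* bᵢ = (b₀, b₁, b₂) ~ N(0, Σ) — subject random intercept and slopes,
  unstructured 3×3 covariance.
* ε_ij ~ N(0, σ²) iid.  The residual family is a modelling choice; Gaussian
  is the standard one for calibrated scale measurements.

With three arms this is exactly ten fixed effects (1 + 3 + 3 + 3).

Priors beyond the change-points are weakly informative defaults, stated in
`model.Priors`: β₀ ~ N(0, 10²) kg after internally centring the weights,
slopes ~ N(0, 1) kg/day, σ ~ half-N(5) kg, and Σ parameterized by its
Cholesky factor L with half-Normal(15, 0.1, 0.1) priors on the diagonal
(kg, kg/day, kg/day) and N(0, 0.1) on the off-diagonal elements.  Putting
the prior on L rather than on a scale/correlation decomposition keeps the
log-Cholesky sampling parameterization one-to-one with the prior and
guarantees positive-definiteness by construction; at these scales the
implied correlation prior is close to uniform.

## Inference

The sampler (`inference.sample_posterior`) is a blocked MCMC scheme that
exploits the model's structure instead of a generic sampler:

1. **Marginalization.** At fixed τ the model is a linear mixed model, so the
   subject effects are integrated out analytically: per subject,
   wᵢ ~ N(Xᵢβ_g, XᵢΣXᵢᵀ + σ²I).  Sampling runs on the marginal posterior of
   (β, τ, Σ, σ) — 17 quantities — instead of the 17 + 3S joint space.
2. **Gibbs for the linear block.**  Given (τ, Σ, σ), the seven linear fixed
   effects have a Gaussian full conditional (a GLS draw), sampled exactly.
3. **Adaptive Metropolis for the rest.**  Each τ_g touches only its own
   arm's likelihood, so it gets an independent 1-D random-walk update on
   logit((τ−50)/200) with its step size adapted toward 44% acceptance.
   (log-Cholesky Σ, log σ) are updated jointly with a 7-D random walk whose
   covariance is adapted (Haario-style) toward 30% acceptance.  All
   adaptation happens during warm-up only; the retained chain is a valid
   Markov chain.
4. **Subject effects.**  For every retained draw, bᵢ is drawn exactly from
   its Gaussian conditional, which restores draws from the full joint
   posterior.

Defaults mirror the analysis plan this package operationalizes: 4 chains ×
10,000 iterations, half warm-up.  The validation experiments use shorter
chains (stated below) because the blocked sampler reaches effective sample
sizes of several hundred per fixed effect within ~1,000 retained draws.
Initialization is least squares with τ pinned at 150 days, jittered per
chain; a non-finite initial state is re-drawn up to 20 times.

Convergence is summarized by rank-normalized split R-hat and ESS (via
ArviZ), with a "converged" gate of R-hat < 1.01 on all ten fixed effects.

**Known limitation — boundary variance components.**  When the true Σ is
(near) zero the posterior of log-scale Cholesky elements has a long flat
ridge toward −∞ and mixes slowly; R-hat on Σ components is then pessimistic
even though fixed-effect estimates are stable.  This regime appears only in
degenerate synthetic cohorts, and the test suite uses realistic
between-subject variation when it asserts convergence diagnostics.

## GWG estimation

For each posterior draw, μᵢ(t) is evaluated from that draw's fixed and
subject effects; GWG(t) = μᵢ(t) − μᵢ(0) (the intercept cancels exactly, so
GWG(0) ≡ 0).  Point estimate = posterior mean; uncertainty = central 95%
interval.  Prediction past a subject's delivery day follows the fitted line
without truncation — that is precisely the standardization to 40+0 weeks.
Group summaries follow the trial's frequentist workflow: normal-theory
t-intervals on the subject-level point estimates, one-way ANOVA across arms,
Tukey HSD pairwise contrasts.  A fully Bayesian group contrast would also be
defensible; the frequentist route was chosen to mirror the analysis this
package reproduces.  Subjects lost to follow-up contribute their observed
records only (missing-at-random within the model; no imputation).

The complete-case comparator (`gwg.complete_case_gwg`) is the traditional
delivery-weight minus self-reported pre-pregnancy weight, computed only for
subjects with a delivery measurement.

## Outcome statistics

Pearson χ² (no continuity correction — verified to reproduce, to three
printed decimals, six published outcome rows from the motivating trial at
arm sizes 34/74/70), one-way ANOVA, Tukey HSD, tie-corrected
Kruskal–Wallis, two-sided Wilcoxon rank-sum (exact enumeration when both
arms have n ≤ 8 and no ties, Normal approximation with continuity and tie
correction otherwise), step-down Holm adjustment, and OLS slopes with
t-based intervals for the physical-activity association and the
COVID-period / clinic-scale sensitivity analyses.  A handful of very sparse
published rows (e.g. events in 1–3 subjects) are *not* reproduced by plain
Pearson χ² and are consistent with an exact variant; no attempt is made to
force agreement there.

## Birth-weight z-scores

Expected fetal weight is the sex-specific fourth-degree polynomial in GA
(days) of the Scandinavian ultrasound-based intrauterine reference, with
reference SD equal to 12% of the expected weight:
z = (BW − MW)/(0.12·MW).  SGA/LGA are the 10th/90th percentiles assuming a
Normal reference, i.e. |z| > 1.28155.  The polynomial coefficients are
embedded as named constants (valid GA range 154–301 days) and pinned by
regression tests; they are configuration taken from the published
reference, not re-derived here.

## Synthetic cohort generator

`cohort.generate_cohort` emulates the trial design the analysis assumes:

* **Allocation 1:2:2** (CON:EXE:MOT).  The intervention arms get their
  floored quotas ⌊2n/5⌋ and the control arm absorbs the remainder, then the
  label vector is randomly permuted.  At n = 219 this reproduces the
  realized arm sizes (45, 87, 87) deterministically.
* **Visit schedule**: self-reported pre-pregnancy weight at GA 0 (residual
  noise plus self-report noise, SD 2 kg), a baseline clinic visit uniform in
  days 43–105 (enrolment ≤ 15+0 weeks), visits in windows 196–202 and
  238–244 days (28+0–6 and 34+0–6 weeks; recorded as 'home' during the
  COVID period), and a delivery weight at the delivery day.
* **Delivery GA** ~ N(280, 12²) days truncated to [196, 300]; **dropout**
  Bernoulli(0.19) with a uniform dropout day between baseline and delivery
  (non-completers keep their earlier records, lose the delivery record).
* **Trajectory truth** (defaults): β₀ = 68 kg, slopes 0.020 → 0.072 kg/day
  at τ = 100 days (≈ 15 kg total gain at 280 days, matching published
  three-arm cohorts); between-subject SDs 12 kg, 0.010 and 0.023 kg/day,
  chosen so the total-GWG SD is ≈ 4.3 kg — the value implied by the
  reference trial's reported group CI widths.  Residual SD σ = 0.8 kg: no
  published value exists for within-subject weight-measurement noise, so
  this is a free parameter representing scale precision plus daily
  physiological fluctuation.
* **Outcomes**: binary outcomes Bernoulli at published pooled rates (GDM
  7%, induction 30%, epidural 33%, ...); mode of delivery multinomial;
  durations and haemorrhage volume log-normal matched to published medians,
  missing for caesarean deliveries (realistic structural missingness);
  birth weight generated as MW(GA, sex)·(1 + 0.12·z) with z ~ N(0,1), so
  SGA/LGA frequencies are 10% by construction.  The prolonged-second-stage
  flags are derived from the drawn durations; the haemorrhage > 1000 ml
  flag is an independent Bernoulli (the published volume quantiles and the
  published exceedance rate are not consistent with any single log-normal,
  mirroring the fact that the two are measured differently in practice).
* **Reproducibility**: one master seed; each participant gets a sub-stream
  derived by stable hashing of (seed, id), so output is bit-identical given
  the seed and independent of generation order.

What the generator does **not** emulate: intervention effects on physical
activity or adherence, wearable-device time series, measurement-device
biases that drift over time, informative dropout, and covariate structure
(parity, BMI) in the trajectories.  Passing tests therefore demonstrate
internal statistical correctness of the pipeline under the stated data
model, not robustness to those real-data features.

## Validation experiments (problem sizes)

Run by `tests/test_acceptance.py` and `scripts/acceptance.py`:

1. **Fixed-effect recovery** — 5 replicate cohorts, 60 subjects, true
   τ = (110, 140, 170) days with arm-distinct slopes, sampler 4 × 2,000
   iterations: all ten fixed effects must be covered by their 95% credible
   intervals in ≥ 4 of 5 replicates.
2. **Printed-row reproduction** — the six Pearson χ² p-values from the
   published count rows, exact to 3 decimals.
3. **Oracle equivalence** — marginal likelihood vs 2-D quadrature (1e-4);
   broken-stick continuity at τ (machine precision); Holm and rank-sum
   enumeration oracles.
4. **Prior recovery** — prior-only run, 4 × 2,000: thinned τ draws pass a
   KS test against Uniform(50, 250) at α = 0.01.
5. **Complete-case consistency** — fully observed cohort, σ = 0.1 kg, no
   self-report noise: arm means of complete-case and model GWG at delivery
   within 0.5 kg.
6. **Null calibration** — 200 no-effect replicates, 45 subjects each,
   reduced sampler (2 × 600): ANOVA on model-estimated total GWG rejects at
   5% within 3 binomial SEs.  Posterior-mean estimates are mildly shrunken
   toward arm means, which in principle inflates the F statistic; at the
   generator's realistic between-subject GWG SD (≈ 4.3 kg) against a ≈ 1 kg
   per-subject estimation error the shrinkage factor is ≈ 0.95 and the
   test stays calibrated, which is exactly what this experiment verifies.

## Numerical notes

* Likelihood work is batched per arm over subjects with padded arrays;
  padded slots are algebraically cancelled, not approximated.
* Per-subject covariance factorizations are 3–7-dimensional Cholesky
  decompositions; no numerical integration is used anywhere in the fit.
* Degenerate inputs: σ ≤ 0 raises in likelihoods; Σ is PSD by construction
  in the sampler and validated on input elsewhere; ties and degenerate
  groups raise informative errors in the outcome statistics rather than
  returning NaN.
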