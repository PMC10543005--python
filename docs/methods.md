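# Methods

## The twin mixed model

All group-level inference runs through one model family. For an outcome
`y` (a pain rating or a neuromarker score, z-scored within modality) on a
3 (stimulus level) × 2 (placebo/control) within-participant design:

```
y_ijk = x'_ijk β + x'_ijk b_f(i) + x'_ijk b_i + ε_ijk
```

where `x = (1, level, condition)` uses centred codes (level −0.5/0/+0.5,
condition −0.5 control / +0.5 placebo; the optional interaction is the
product of the codes and enters the fixed part only), `b_f ~ N(0, Σ_f)` is
shared by all members of family `f`, and the individual vector `b_i` is
drawn from `N(0, Σ_mz)` or `N(0, Σ_dz)` according to zygosity. Encoding
duplicates the individual random columns into an MZ copy and a DZ copy with
the off-zygosity copy identically zero, and the random-effect covariance is
block diagonal by zygosity — the heteroskedastic twin structure that keeps
fixed effects from being biased toward the more variable DZ group.
Individual-difference models (brain–behavior, expectation, transfer) use
the same machinery with the predictor of interest replacing the placebo
code in both fixed and random parts.

Singletons: participants without a co-twin load on the family block only.
With one member per family the family and individual draws are not jointly
identifiable, so the individual draw is fixed at zero, in the generator and
the model alike.

Residuals are iid by default. An optional residual-*group* column gives
each group its own variance; this expresses classic heteroskedastic
problems (it is how the Welch oracle fixture is encoded) and is off in all
pipeline analyses.

### Estimation

REML, profiled over the residual scale. Each covariance block is
parameterized by its Cholesky factor with log diagonal (positive
semidefinite by construction; 6 free parameters per 3×3 block, 18 total in
the default model). The optimizer is L-BFGS-B on the profiled criterion
with central-difference gradients (step 1e−5), convergence at projected
gradient < 1e−6, and up to 3 perturbed restarts; variance ratios at the
boundary are flagged, not errored. Because families are independent, the
criterion is assembled from per-family cross-products (U'U, U'X, U'y)
computed once per dataset; an evaluation then costs only small dense
algebra batched over families, so the cost is essentially independent of
the number of trials. A (near-)perfect fit clamps the residual sum of
squares at a relative floor of 1e−12 so the GLS solution remains
recoverable.

### Satterthwaite degrees of freedom

For a contrast `c`, `df = 2 f² / Var(f)` with `f(θ) = c'(X'V⁻¹X)⁻¹c`.
`Var(f)` comes from the delta method: the gradient of `f` in the
unconstrained variance parameters (central differences, step 1e−5) against
the inverse observed REML information. The information Hessian uses a
larger second-difference step (2e−4): the criterion is O(n), so a 1e−5
step would leave roundoff noise of order 1e−6 in the Hessian, visibly
corrupting df in the closed-form checks; 2e−4 balances roundoff against
truncation (empirical df error ~6e−7 on the iid fixture). Singular
information yields df = ∞ with a warning and a normal-approximation p;
this occurs legitimately when variance components sit on the boundary.

On fixtures the df reproduces n−1 for the iid intercept-only problem and
the Welch–Satterthwaite formula for two groups with separate residual
variances, and the REML point estimates match closed-form ANOVA components
on balanced one-way data and an independent mixed-model implementation
(statsmodels MixedLM, used as a test oracle only) on single-zygosity data.

### Interaction protocol

Each outcome is fitted with the level × condition interaction first; if the
interaction p ≥ .05 the mains are reported from the refitted model without
it (for interpretability), otherwise from the full model. Both fits are
retained and every reported row records which model supplied it.

## Bayes factors

Nested-model JZS construction on the standardized outcome. The full model
holds the fixed mains (optionally plus the interaction) and random
*intercepts* for family and for participant split by zygosity — no random
slopes; the null is the full model minus the effect of interest (the
interaction, when included, stays in both models when a main effect is
tested). Priors: flat on the intercept, Jeffreys on σ²; each non-intercept
fixed effect gets an independent Cauchy prior on its standardized
coefficient via the scale mixture β|g ~ N(0, gσ²), g ~ r²/χ²₁ — with the
requested `rscale` (default 1) for the effect of interest and the nuisance
scale 1 for other fixed covariates, mirroring the scaled-inverse-chi-squared
treatment of the random-intercept variance ratios. This uniform treatment
of non-interest covariates was a genuinely open choice; flat priors would
also cancel between the models, but proper nuisance priors keep every
marginal likelihood finite on its own.

Conditional on the g vector the model is Gaussian and the marginal over
(intercept, σ²) is closed form; the remaining low-dimensional g integral is
importance-weighted Monte Carlo. Prior draws turn out to be a hopeless
proposal once random-intercept posteriors concentrate, so the proposal is a
multivariate t (7 df) centred on the mode of the log-g posterior kernel
with Laplace covariance (curvature eigenvalues clipped to [1e−2, 1e6] and
the scale inflated by 1.2 so the proposal over-covers), plus up to three
adaptive re-centring rounds if the weight effective sample size falls below
5% of the draws; exhausting adaptation is an error, never a silent result.
The reported proportional error combines the two delta-method MC standard
errors in quadrature. In the one-sample reduction the machinery reproduces
the classic JZS t-test Bayes factor (one-dimensional quadrature oracle) —
the module's correctness anchor.

Evidence labels follow the conventional Jeffreys-style bands (anecdotal /
moderate / strong / very strong / extreme at 3, 10, 30, 100 and their
reciprocals); odds strings round the (inverse) Bayes factor to an integer.
The robustness grid is `r ∈ {√2/2, 1, √2}` × interaction {absent, present};
a printed prior-scale list this grid was derived from contains an apparent
duplicated value, and the three distinct scales are implemented.

## The synthetic cohort

The generator is the ground truth for every downstream test. It emulates:

* a cohort of MZ pairs, DZ pairs and singletons (defaults 142/160/93
  individuals, i.e. 71 + 80 + 93 families);
* 32 trials per participant over 4 runs in control–placebo–placebo–control
  order, 4 thermal + 4 mechanical per run; within each modality × condition
  cell the 8 trials cover the three stimulus levels as 3+3+2 with the
  short level rotating across participants;
* outcomes generated on the z scale from the same model the pipeline fits —
  fixed effects (defaults: thermal intensity 0.409, thermal placebo −0.359,
  mechanical 0.202/−0.244, zero interaction), a family draw
  (Σ_f = diag(0.50², 0.15², 0.20²)), zygosity-specific diagonal individual
  draws (SDs 0.30/0.10/0.10 for MZ, 0.45/0.15/0.15 for DZ — DZ more
  variable, as the model assumes) and residual SD 0.75. Where no value was
  externally fixed, these were chosen once to give plausible familial
  intraclass correlations (≈0.2–0.3) and total unit-order variance, and not
  revisited;
* gLMS-style ratings: the latent z-scale outcome mapped affinely
  (0.22 + 0.10·z) into [0, 1] and clipped, with the clipped fraction logged
  (≈1% at the defaults). The latent column is retained so recovery studies
  can fit the exact generative scale; the distribution of ratings on the
  gLMS is a stand-in, not an inference about real data. Unpleasantness is
  intensity plus N(0, 0.35²), giving a within-participant correlation near
  0.9;
* reaction times with a configurable fraction (default 0.47%) planted
  outside the (0.02, 5.01) s validity window, rounded to an exact count for
  deterministic QC tests;
* signature volumes: disjoint cubic subregions with all-positive or
  all-negative weights (defaults 2 positive + 6 negative) on a ≥8³ grid,
  and contrast maps `w·(target/‖w‖²) + noise` whose masked dot product
  recovers the planted score in expectation.

Randomness derives from one root seed through documented
`SeedSequence(seed, spawn_key=...)` child streams per purpose and per
(participant, run), so adding participants never perturbs other streams and
identical seeds give bit-identical tables and volumes.

What the generator does **not** emulate: raw BOLD time series (the GLM
module builds its own small fixtures), physiological noise, scanner drift
beyond the drift basis, skewed/heaped rating distributions, conditioning
dynamics, or missingness other than RT-based exclusions. Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to real-world artefacts.

## First-level GLM

SPM-convention double-gamma HRF (response peak 6 s, undershoot 16 s, unit
dispersions, ratio 6, 32 s support), sampled at the TR (default 0.46 s) and
normalized to unit peak. The high-pass filter is a discrete cosine basis
with a 180 s cutoff period — a nominal "180 Hz" specification is physically
impossible at this TR and is read as 180 s. Censoring (8 lead frames plus
detected spikes) uses per-frame indicator columns, numerically equivalent
to row deletion but solvable in one pass (verified numerically). The spike
detector — robust z of the global mean signal at threshold 3.5 — is a
documented, configurable substitute for scanner-specific tooling. Cue
regressors are modelled as 0.5 s events. Rank deficiency is reported with
the names of the collinear columns, never silently dropped.

## Scoring conventions

Maps and signatures must share grid and affine (tolerance 1e−4 per
element); nothing is ever resampled implicitly, because silent resampling
changes dot products — an explicit, warning-emitting `regrid` utility
exists for deliberate use. Score masks are the intersection of map and
signature masks. For negative-weight subregions a more positive local
pattern response means deactivation; the sign legend travels with the
atlas. Within-group z-scoring uses the sample (n−1) SD and refuses constant
groups by name.

## Quality control

Trials are dropped when the rating reaction time is strictly above 5.01 s
or strictly below 0.02 s (boundary values retained; missing values count as
non-responses). Participants are then dropped if any modality × condition
cell retains fewer than two of the three stimulus levels. The two printed
phrasings of this rule ("complete sets … for more than one stimulus level"
and "full data for at least two stimulus levels") are reconciled as that
post-condition. Trial exclusion runs before the participant rule, and
counting happens after trial exclusion; both filters are idempotent and
fully logged.

## Validation studies and problem sizes

The operating-characteristic studies run at scaled problem sizes chosen as
the package's own desk-scale defaults, preserving the cohort's MZ:DZ:singleton
mix:

* recovery/coverage: 200 cohorts of 100 families (162 participants),
  thermal placebo planted at −0.359 on the latent scale; mean estimate
  within 2 Monte Carlo SEs of truth and 95% CI coverage in [0.93, 0.97];
* type-I error: 1,000 cohorts of 65 families with a zero placebo effect;
  generation and fit use zygosity-split random *intercepts* (slope SDs
  zero), which keeps the loop cheap while still exercising the
  heteroskedastic machinery; the full random-slope structure is covered by
  the recovery study;
* null Bayes factors: 11 cohorts per cell of the 3 × 2 robustness grid;
  every cell's median BF₁₀ is required to stay below 1/3.

## Known limitations

* The Satterthwaite information uses finite differences; at variance
  boundaries it can be singular, in which case df = ∞ (normal
  approximation) is reported with a warning rather than a guess.
* The Bayes-factor integrator assumes the g posterior is unimodal enough
  for a t proposal after adaptation; pathological multimodality would
  surface as an effective-sample-size error, not a wrong number.
* Only the two model shapes used by the analyses (factorial mains ±
  interaction; individual-difference slope models), plus fixed-only
  covariates, are supported — there is deliberately no general formula
  parser.
* Covariate robustness models add covariates to the fixed part only;
  random terms for covariates are not supported.
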