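# Methods

## The model

`egfrdp` models longitudinal estimated glomerular filtration rate (eGFR,
mL/min/1.73 m²) in type-2-diabetes patients as a population
disease-progression process.  For subject *i* at time *t* (years since
T2DM diagnosis) the structural forms are

* linear: `S_i(t) = S0 · exp(η_{S0,i}) · (1 + α · exp(η_{α,i}) · t) · M(x_i(t))`
* Emax-in-time: `S_i(t) = S0 · exp(η_{S0,i}) + Smax · t / (S50 + t)`

with `M(x) = 1 + Σ_k θ_k (x_k − x_k^ref)` a multiplicative covariate
factor (binary drug/comorbidity flags referenced at 0; fasting blood
sugar centered at 7.4 mmol/L).  `α` is a *fractional* rate of change per
year; the absolute rate in eGFR units is `S0·α`.  The same multiplicative
form is used for the base model (empty covariate set, `M ≡ 1`) and every
covariate model, so all covariate models are nested in each other and in
the base — a requirement for valid likelihood-ratio testing.

Between-subject variability (BSV) is exponential (log-normal) on baseline
and rate.  This preserves sign — every subject's baseline is positive and
every subject's rate has the sign of `α` — and makes the typical value
the subject-level median.  BSV is reported as `100·sqrt(ω²)` %.  No BSV
is placed on `Smax`/`S50`.  Residual error is additive (SD in eGFR
units), proportional (fractional SD), or combined.

## Estimation (FOCE-I)

`marginal_ofv` implements the first-order conditional estimation method
with interaction.  Per subject, the conditional modes (MAP etas) are
found by a damped Gauss–Newton iteration (inner gradient tolerance 1e-8,
deterministic two-point start rule: warm start vs zero, better one wins).
The model is linearized around the modes, the residual variance is
evaluated at the individual predictions (interaction), and the subject's
contribution is `log|C| + rᵀC⁻¹r` with `C = GΩGᵀ + diag(V)`.  The
additive constant `N·log 2π` is excluded, so only ΔOFV is comparable
across implementations; `include_constant=True` restores it, and a test
verifies ΔOFV is identical either way.

All subjects are evaluated simultaneously on padded rectangular arrays
with closed-form 1×1/2×2 linear algebra; a full-cohort objective
evaluation is a few milliseconds, which is what makes the stepwise
covariate search affordable.  A subject whose inner line search stalls
keeps its best iterate and is flagged.

`quadrature_ofv` is an independent oracle: exact −2 log marginal
likelihood by adaptive Gauss–Hermite quadrature (mode- and
curvature-adapted, tensor grid, log-sum-exp), used in tests to bound the
FOCE approximation error on small instances.  It is never used as the
estimator.

`fit_model` minimizes the OFV with L-BFGS-B.  Variances and residual SDs
are optimized on the log scale; structural parameters on a scaled
identity (scale = initial magnitude) so the optimizer sees O(1)
coordinates; `S0` is bounded positive.  A variance initialized at exactly
zero is treated as structurally absent (this is how the fixed-effects /
OLS-equivalence limit is expressed).  Initial values are data-driven:
baseline from mean earliest observations, rate from the pooled OLS slope
as a fraction of baseline, residual SD from pooled OLS residuals,
baseline BSV from the moment estimate `Var(log first observation)`.

The rate-BSV direction of this likelihood is prone to local optima and
ridge-shaped flatness (see *Identifiability*, below).  `fit_model`
therefore always runs a deterministic second start at `ω²_α = 1` whenever
rate BSV is estimated, restarts L-BFGS-B from its own solution until the
OFV improves by < 0.01 (resetting the Hessian approximation), and keeps
the lowest-OFV solution.  No covariance step is attempted; SIR is the
supported uncertainty path.

## Stepwise covariate modeling

Univariate screening fits base-plus-one-covariate for each candidate.
Forward addition iteratively adds the candidate with the largest OFV drop
exceeding the chi-square critical value at p < 0.05 and 1 df (3.84);
backward elimination removes the cheapest covariate while removal costs
no more than the p < 0.01 value (6.63).  Each covariate contributes one
coefficient, hence 1 df throughout.  Every step refits all parameters,
warm-started from the parent estimates; exact ties break by candidate
list order.  Non-nested structural comparisons use AIC = OFV + 2·(number
of estimated parameters), ties preferring the first argument.

## Synthetic cohorts

The generator emulates the study design: 251 subjects, 6-month visits
from diagnosis, at most 6.6 years of follow-up, ~3241 observations in
total; an external cohort of 109 subjects.  Per-subject visit counts are
`2 + Binomial(12, p)` with `p` set so the mean count is
`target_obs / n_subjects` (≈ 12.9) — follow-up truncation on the visit
grid, with no explicit dropout process.  Binary covariates are
subject-constant Bernoulli draws.  Gender (0.617 male), smoking (0.171)
and the nephropathy fraction (96/251) follow the study demographics;
drug exposures are not reported there, so the defaults (metformin 0.8,
statin 0.6, ARB 0.3, CVD 0.2) are plausible T2DM-clinic values and fully
configurable.  FBS is a subject mean — Normal(9.1, 3.1) mmol/L in the
nephropathy group, Normal(7.8, 2.2) otherwise — plus independent
visit-to-visit noise with SD 1.5 mmol/L (fasting glucose is highly
variable day to day in T2DM), floored at 0.5 mmol/L.  Trajectories come
from a truth parameter set and spec; reference truths are provided for
the base model (S0 84.5, α −0.0021/yr, BSV 19.3 %/180.8 %, σ_add 6.46)
and the five-covariate final model (S0 84.6, α −0.0041/yr, θ: metformin
0.029, FBS −0.0038, ARBs 0.0361, statin 0.0314, CVD −0.0925, BSV
18.7 %/157.8 %, σ_add 6.29).

A single master seed is split into named substreams (visit counts,
covariates, etas, residuals); the external cohort uses a disjoint set of
substreams of the same seed and a disjoint id range.  What the generator
does **not** emulate: informative dropout, missingness (source records
had < 5% missing, handled upstream), covariate–trajectory feedback (drug
start in response to declining eGFR), correlation between covariates, or
nephropathy onset as an event process.  Passing recovery tests therefore
shows the estimator is correct under the stated generative model, not
that the clinical estimates themselves are unbiased.

## Diagnostics

VPC: replicates are simulated on the observed design (times and
covariates fixed, fresh etas and residuals), binned on the visit grid
(half-interval edges), and summarized at the 5th/50th/95th percentiles
(1000 replicates by default).  The band per (bin, level) cell is the
2.5–97.5 % range of the replicate percentiles; cells flag whether the
observed percentile falls inside.  Percentiles use numpy's linear
interpolation of order statistics so results are bit-stable.  As the
replicate count grows the band converges to a fixed interval — it does
not shrink — while the Monte-Carlo noise of its edges does shrink; the
test suite checks the latter.  External validation runs the same VPC on
the external cohort with parameters frozen from the internal fit.

GOF tables report PRED (etas 0), IPRED (at the EBEs), IWRES
(IPRED-standardized residuals) and CWRES (FOCE-linearized marginal
residuals decorrelated by the Cholesky factor of the subject's linearized
covariance; approximately iid N(0,1) under a correct model).

## SIR uncertainty

Parameter vectors are drawn from a multivariate-normal proposal on the
estimation transform scale, weighted by `exp(−0.5·OFV)` over the proposal
density, and resampled **without replacement**.  The default schedule is
two stages, (1000 samples → 500 resamples) then (2000 → 1000), each stage
rebuilding the proposal from the previous stage's resample moments.  With
no covariance matrix available the first proposal is independent normals
with 30 % relative SD per parameter — deliberately over-dispersed, as SIR
practice recommends; an effective sample size below 5 % of the draws
triggers a warning to inflate.  RSE% = 100·SD(resamples, natural scale) /
|point estimate|, with variances summarized on the SD (ω) scale.

## Identifiability at the reference truths

At the reference truth values the design carries little information about
the typical rate: a single subject's OLS slope has SE ≈ 0.011 fractional/
year against a typical magnitude of 0.0021, so the median/spread
decomposition of the signed-lognormal rate distribution (ω_α = 1.8) rests
entirely on the minority of fast progressors.  Repeated simulation–refit
experiments with this package show `S0`, baseline BSV and `σ_add`
recover closely, while `α` concentrates near −0.005 with BSV_α near 130 %
(the exact-likelihood oracle behaves similarly, so this is a property of
the experiment, not of the FOCE approximation alone).  Likewise, because
a subject-constant multiplicative covariate is confounded with baseline
BSV, drug-flag effects of the magnitude in the final truth set (θ ≈ 0.03
against ω_S0 ≈ 0.19) carry expected ΔOFV of only ~1–3 at 251 subjects:
the covariate search has high power only for FBS (time-varying) and CVD
(largest effect).  The same confounding makes the final model's typical
baseline trade off against the prevalence-weighted covariate mix along a
nearly flat likelihood ridge, so its simulation-based SE (~4.3 eGFR
units across refit replicates) is several times the base model's (~0.8).
These analyses are reproduced by the test suite and acceptance script
rather than asserted.

## Numerical choices and limitations

* Inner tolerance 1e-8 (gradient), outer ftol 1e-11 / gtol 1e-6 —
  tighter inner than outer is required for stable FOCE gradients.
* Covariate multipliers must stay positive; a violation raises instead of
  silently flipping the prediction's sign.
* Degenerate likelihoods (all residual SDs zero) are rejected; boundary
  variances (ω² → 0) are reported, not errors.
* Problem sizes in the shipped tests (cohorts of 5–251 subjects, VPC at
  up to 1000 replicates, SIR toys at 10⁴ draws) were chosen to exercise
  every code path at desk scale.
* Not implemented: prediction-corrected VPC, npde, bootstrap/profile
  likelihood uncertainty, multiple imputation of missing records, eGFR
  derivation from creatinine, and NONMEM control-stream compatibility.
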