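# Methods

## The problem

Randomized trials of PARP-inhibitor maintenance therapy in recurrent
ovarian cancer report progression-free survival (PFS) as Kaplan-Meier
curves, not individual event times. A model-based meta-analysis pools
such arm-level aggregate data through a parametric survival model: each
digitized point is a survival fraction at a time, carrying binomial
sampling error that scales with the arm's size, and the trials differ
systematically (drug, biomarker population, monotherapy vs combination
with chemo- or anti-angiogenic therapy), which the model absorbs through
covariates and study-level random effects. Because the original digitized
tables are not publicly deposited, this package pairs the estimator with
a synthetic-data generator that reproduces the cohort's structure
exactly, so every stage of the analysis is testable end to end.

## Model

Four hazard families are implemented; `h(t)` is the instantaneous
progression/death rate (per month) and `S(t) = exp(-∫₀ᵗ h(u) du)`:

| family       | h(t)                          | S(t) closed form                |
|--------------|-------------------------------|---------------------------------|
| exponential  | λ₀                            | exp(−λ₀ t)                      |
| Gompertz     | λ₀ e^{βt}                     | exp(−λ₀ (e^{βt}−1)/β)           |
| Weibull form | λ₀ e^{β ln t} = λ₀ t^β        | exp(−λ₀ t^{β+1}/(β+1)), β > −1  |
| log-normal   | φ(z)/(σ t Φ(−z)), z=(ln t−μ)/σ| Φ(−z) = 1 − Φ((ln t − μ)/σ)     |

The Gompertz β → 0 limit is a removable singularity, handled by a series
branch below |β| < 1e−8. The log-normal hazard divides by the survival
fraction, which is tiny at late times; it is computed through
`log_ndtr(−z)` (complementary form) to avoid cancellation. The
"Weibull form" is kept exactly as the log-time regression
h = λ₀ e^{β ln t} — a Weibull hazard with shape β + 1 — rather than
re-parameterized to the usual shape/scale pair. μ is the location of
ln(time): the median survival time of the log-normal family is e^μ, and
σ is the log-time scale, not the standard deviation of the time
distribution.

### Hierarchy and residuals

Study-level heterogeneity acts multiplicatively on the family's positive
parameters (`P_i = P_pop · e^{η_i}` with η ~ N(0, ω²)): on μ
and σ for the log-normal family (diagonal Ω — no covariance is
estimated), on λ₀ otherwise. Covariates scale parameters
multiplicatively too: `P_pop = P_typ · (1 + θ)` off the reference level
of a categorical covariate, `P_pop = P_typ · e^{(COV − COV_median)·θ}`
for a continuous one; multiple effects compose multiplicatively. The
reference model places the therapy-type effect on μ with combination
therapy as the reference level, so monotherapy has μ scaled by
(1 + θ_combo) with θ_combo ≈ −0.215.

An observed fraction at time j in study i is modeled as

    Obs = Pred · (1 + SE · ε₁) + SE · ε₂

with ε₁ ~ N(0, ε_prop²), ε₂ ~ N(0, ε_add²) and SE the binomial standard
error `sqrt(p(1−p)/n)` of the fraction. The residual variance is
therefore `SE² (Pred² ε_prop² + ε_add²)`; the Gaussian is not truncated
to [0, 1] (predictions are bounded, observations are not).

Two choices inside that variance deserve note:

* **Which p enters SE.** The package evaluates SE at the current model
  prediction (`se_weighting="model"`, the default). Plugging in the
  observed fraction — the other supported mode — makes the weight
  correlate with the noise it weights, which biased μ, σ and ε_add
  downward by 4–7% in recovery experiments; with model-based SE these
  medians recover within ~2%. The generator uses the noiseless
  prediction, so the default also matches the generating process.
* **Boundary fractions.** A fraction clipped to exactly 0 or 1 has
  binomial SE 0 and would zero the residual variance, so the weighting
  SE clamps p to [0.5/n, 1 − 0.5/n] (a half-count continuity floor).
  Interior observations are unaffected, and the corpus's stored `se`
  column remains exactly `sqrt(p(1−p)/n)`.

### Estimation

The marginal likelihood integrates each study's η out of the penalized
Gaussian joint density. The integral is approximated by the Laplace
method at the conditional mode (found by a damped Newton search with
finite-difference derivatives, warm-started across outer iterations);
because the residual variance depends on the prediction, the
η-dependence of the variance is retained, in the spirit of conditional
estimation with interaction. The objective function value (OFV) is
−2 log of that marginal likelihood. On small corpora (3 studies, ≤ 4
points per arm) the Laplace OFV agrees with a 9-node adaptive
Gauss-Hermite quadrature within < 0.1 units; on the full reference
design the two differ by a few units but by a nearly constant offset, so
OFV *differences* — everything selection and likelihood-ratio reasoning
use — are preserved.

The outer problem minimizes the OFV over transformed parameters (log
scale for σ, ω, ε components; log(1+θ) for categorical covariate
effects, which enforces θ > −1) with L-BFGS-B, starting from
moment-style heuristics (μ from the interpolated median of the observed
curves, σ = 1, ω = 0.1, ε_prop = 0.3, ε_add = 1.0); up to two seeded
jittered restarts fire if the first run fails. Standard errors come from
the central-difference Hessian of the OFV (covariance = 2 H⁻¹),
delta-transformed to the natural scale and reported as percent of the
estimate. Empirical Bayes estimates (EBEs) are the per-study conditional
modes at the optimum, with conditional variances from the inner Hessian.

### Covariate selection

Forward inclusion accepts, at each step, the candidate with the largest
OFV drop if it exceeds 2.71 (χ²₁ at p < 0.1; near-ties under 1e−6 go to
declaration order); backward elimination then removes any covariate
whose deletion fails to raise the OFV by more than 3.84 (p < 0.05),
iterating to stability. Multi-level categorical covariates enter as one
θ per non-reference level and are tested jointly against the same
scalar thresholds. Continuous covariates with blanks are imputed with
the patient-weighted median; a covariate missing in arms totalling more
than 30% of patients is excluded from the candidate set. Covariates are
tested on μ only by default (the reference model's finding), but any
family parameter can be targeted.

### Diagnostics

* **GOF / CWRES**: population (η = 0) and individual (η = EBE)
  predictions per observation; conditional weighted residuals decorrelate
  each study's residual vector with the first-order covariance
  G Ω Gᵀ + V around the EBE (G = ∂Pred/∂η by central differences,
  Cholesky whitening).
* **VPC**: corpus replicates (default 1,000) simulated from the fitted
  model on the observed design; 2.5/50/97.5 percentile bands per
  (arm, time) from the untruncated simulated fractions; coverage is the
  share of observations inside their own 95% band.
* **Bootstrap**: studies (not arms) are the resampling unit, preserving
  within-study correlation; percentile CIs over converged replicates.
  Optional stratified resampling keeps sparse strata (the two
  combination-therapy studies) represented. The analysis driver runs 200
  replicates, a scaled-down size this package adopts for its own runs.
* **Sensitivity**: refit after dropping open-label arms
  (`blinded == False`), refusing if fewer than two studies remain.

### Scenario simulation

Each arm's location parameter is μ_i = (covariate-adjusted typical μ) ·
e^{EBE η} with a delta-method SE from the EBE conditional variance. Arms
matching a scenario filter are pooled by DerSimonian-Laird
random-effects meta-analysis (moment τ², weights 1/(se² + τ²), 90% CI
± 1.645·SE). Monte Carlo then draws μ* ~ N(pooled, SE from the CI)
(default 10,000 replicates), evaluates S(t) with σ held at its
population estimate, and reports the per-time median and 5th/95th
percentile band plus the median PFS (= e^{μ*}, the log-normal closed
form) with its 90% CI. The CI level is configurable.

## The synthetic-data generator

`paper_design()` fixes the corpus layout: 8 studies, 12 arms, 1,169
patients, with exact margins — olaparib/niraparib/rucaparib 501/302/366,
BRCAm/BRCAwt/HRD-positive 669/100/400, monotherapy/combination 1,077/92,
64 partially platinum-resistant patients, and combination partners
cediranib/bevacizumab/chemotherapy 43/21/28. Four studies are
open-label. The two randomized combination trials carry paired
monotherapy/combination arms of the same drug, as the trials they mimic
did; the allocation is deterministic so the margins are reproducible
exactly. Generating parameters default to the final-model values
(μ 2.96, σ 0.999, θ_combo −0.215, ω_μ 0.159, ω_σ 0.142, ε_prop 0.429,
ε_add 1.241). The time grid is 3–36 months at 3-month spacing, truncated
where the arm's noiseless survival falls below 0.02 (published KM
figures rarely extend into the deep tail); fractions are clipped to
[0, 1] after noise, with the unclipped latent value kept in the truth
record for calibration tests.

What the generator does *not* emulate: digitization error beyond the
combined residual model, within-arm serial correlation of KM steps
(each point's noise is independent), censoring dynamics, and
non-proportional covariate effects. Passing recovery tests therefore
demonstrate that the estimator inverts its own assumed data-generating
process at the study's scale — not that the model is correct for any
real trial.

## Known limitations

* Maximum-likelihood variance components are biased low at 8 studies
  (no REML-type correction exists for this nonlinear model): ω medians
  sit ~20–25% under truth in 20-replicate experiments, approaching truth
  as the number of studies grows.
* ε_prop is weakly identified at this scale — its variance contribution
  is at most ~9% of the residual even at the earliest time point — so its
  maximum-likelihood estimate is effectively bimodal across replicate
  corpora (near zero or well above the generating value), and any summary
  of it over a modest number of replicates is unstable. Treating
  boundary-clipped fractions as censored removes the clipping component
  of this bias but cannot add information the design does not contain.
* With a Gompertz hazard of β < 0 and λ₀/|β| < ln 2 the survival curve
  plateaus above one half and no median survival time exists; the
  package raises an error rather than extrapolating.
* Scenario medians inherit every approximation upstream (EBE shrinkage,
  pooling normality); single-arm scenarios reproduce that arm's estimate
  with its conditional SE rather than a between-arm spread.
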