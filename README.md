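# pfsmeta

Model-based meta-analysis (MBMA) of progression-free survival (PFS) from
arm-level aggregate data — the setting of PARP-inhibitor maintenance
therapy in recurrent ovarian cancer, where trials report Kaplan-Meier
curves rather than patient-level event times. Digitized KM fractions from
multiple trials are pooled through a parametric hazard model with
study-level random effects, covariate effects are screened by stepwise
likelihood-ratio selection, and treatment scenarios (monotherapy vs
combination therapy, drug, biomarker status) are compared by random-effects
pooling plus Monte-Carlo simulation of median PFS.

The package is aimed at pharmacometricians and evidence-synthesis
statisticians who want an open, scriptable equivalent of this workflow,
with a synthetic-data generator that reproduces the target cohort's
structure so the whole pipeline is testable without the (undeposited)
digitized trial tables.

## Model

Observed survival fractions `Obs_{j,i}` at time `t_j` in study `i` follow

    Obs = Pred · (1 + SE·ε₁) + SE·ε₂          (combined residual, SE-weighted)
    Pred = S(t; P_i),  P_i = P_pop · e^{η_i},  η_i ~ N(0, ω²)

with `SE = sqrt(p(1-p)/N_i)` the binomial standard error and S(t) one of
four parametric survival functions (exponential, Gompertz, Weibull-form,
log-normal). The selected log-normal model has
`S(t) = 1 − Φ((ln t − μ)/σ)`, study-level random effects on μ and σ, and a
categorical therapy-type covariate on μ:

    μ_pop = μ_typ · (1 + θ_combo),   θ_combo < 0 for monotherapy

Estimation maximizes the Laplace-approximated marginal likelihood (the
objective function value, OFV = −2 log L); covariates enter by forward
inclusion (ΔOFV > 2.71) and backward elimination (ΔOFV > 3.84). See
`docs/methods.md` for the full account, including the treatment of
fractions clipped at the [0, 1] boundary as censored observations.

## Worked example

```python
from pfsmeta import (default_truth, generate_corpus, fit, ModelSpec,
                     run_scenarios)

truth = default_truth()                      # 8 studies, 12 arms, 1,169 patients
corpus, record = generate_corpus(truth, seed=1)
model = ModelSpec(covariate_effects=list(truth.covariate_effects))
result = fit(corpus, model, seed=1)
print(result.report())
```

prints (estimate, relative SE in percent):

```
parameter                       estimate       SE%
--------------------------------------------------
mu                                 2.935      3.8
sigma                              1.003      4.1
theta_therapy_type_monotherapy     -0.1988     12.1
omega_mu                         0.08229     27.2
omega_sigma                      0.08621     39.4
eps_prop                          0.7255    104.5
eps_add                            1.233      9.5
OFV: -362.844   converged: True
```

Here `mu` is the log-time location for combination therapy (median PFS
e^2.935 ≈ 18.8 months) and the therapy-type factor −0.199 scales μ down
for monotherapy (e^{2.935·0.801} ≈ 10.5 months); both recover the
generating values (2.96 and −0.215) within their standard errors. The
105% SE on `eps_prop` is honest: the proportional residual contributes at
most ~9% of the residual variance at any time point, so a corpus of this
size barely identifies it. Scenario simulation then pools arm-level
parameters and draws Monte-Carlo replicates:

```python
for s in run_scenarios(result, corpus, n_rep=10000, seed=1):
    lo, hi = s.median_pfs_ci90
    print(f"{s.scenario:12s} median PFS {s.median_pfs:5.1f} months ({lo:.1f}-{hi:.1f})")
```

```
monotherapy  median PFS  11.0 months (9.7-12.4)
combination  median PFS  18.2 months (14.3-23.0)
olaparib     median PFS  14.1 months (11.6-17.2)
niraparib    median PFS  13.8 months (11.7-16.3)
rucaparib    median PFS   8.5 months (8.2-8.9)
BRCAm        median PFS  13.0 months (10.7-15.9)
BRCAwt       median PFS  13.1 months (8.2-21.0)
HRD_positive median PFS  11.2 months (8.6-14.6)
```

Each line pools that scenario's arms by DerSimonian-Laird random-effects
meta-analysis and simulates 10,000 draws of μ from the pooled
distribution; the combination-vs-monotherapy gap (18.2 vs 11.0 months)
reflects the generating θ_combo, while per-drug and per-biomarker spreads
here reflect only which studies' random effects each scenario happens to
contain — the generator assigns those no true effect.

The same pipeline is available as numbered scripts under `analysis/`
(generate corpus → fit → family comparison → covariate selection →
diagnostics → scenario simulation → recovery study), each writing its
tables to `results/`, and as a CLI (`pfsmeta synth|fit|select|gof|vpc|
bootstrap|simulate|report`) driven by a YAML config.

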