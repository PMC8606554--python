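"""Scenario simulation: arm-level parameter pooling and Monte-Carlo PFS bands.

After the mixed-effects fit, each arm gets a location parameter
mu_i = (covariate-adjusted typical mu) * exp(eta-hat of its study), with a
delta-method SE from the conditional variance of the empirical Bayes
estimate.  Arms sharing a scenario label (a covariate filter such as
"monotherapy" or "BRCAm & combination") are pooled by DerSimonian-Laird
random-effects meta-analysis; Monte-Carlo draws from the pooled normal
distribution then give per-time survival bands and the median PFS with its
confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import Arm, Corpus
from .fitting import FitResult
from .hazards import HazardParams, survival

__all__ = [
    "ArmParameterEstimate",
    "PooledEstimate",
    "ScenarioSummary",
    "arm_parameters",
    "random_effects_pool",
    "simulate_scenario",
    "run_scenarios",
]


@dataclass
class ArmParameterEstimate:
    study_id: str
    arm_id: str
    n: int
    mu_i: float
    se_mu_i: float
    scenario_labels: dict

    def matches(self, **filters) -> bool:
        return all(self.scenario_labels.get(k) == v for k, v in filters.items())


@dataclass
class PooledEstimate:
    scenario: str
    pooled_mu: float
    se_pooled: float
    ci90_mu: tuple[float, float]
    tau2: float
    n_arms: int


@dataclass
class ScenarioSummary:
    scenario: str
    pooled: PooledEstimate
    time_grid: np.ndarray
    pfs_band: pd.DataFrame  # columns: time, p5, p50, p95
    median_pfs: float
    median_pfs_ci90: tuple[float, float]
    seed: int

    def row(self) -> dict:
        lo, hi = self.median_pfs_ci90
        return {
            "scenario": self.scenario,
            "median_pfs_months": self.median_pfs,
            "ci_lo": lo,
            "ci_hi": hi,
            "pooled_mu": self.pooled.pooled_mu,
            "tau2": self.pooled.tau2,
            "n_arms": self.pooled.n_arms,
        }


def arm_parameters(fit: FitResult, corpus: Corpus) -> list[ArmParameterEstimate]:
    """Per-arm location parameter mu_i and its SE.

    mu_i applies the fit's covariate model to the arm's profile and scales
    by exp(eta-hat) of the arm's study; the SE is the delta-method
    transform mu_i * sd(eta | data) of the EBE conditional standard
    deviation, floored at a tiny positive value so single-arm pooling stays
    well defined.
    """
    if not fit.converged:
        raise ValueError("arm parameters require a converged fit")
    from .covariates import apply_covariate
    from dataclasses import replace as _replace

    target = fit.model.re_targets[0]  # "mu" for the log-normal family
    re_index = 0
    out = []
    for arm in corpus.arms:
        effs = [
            _replace(e, theta_cov=fit.theta[e.key])
            for e in fit.model.covariate_effects
            if e.target_parameter == target
        ]
        p_pop = apply_covariate(fit.theta[target], arm.covariates, effs)
        eta = fit.ebe.get(arm.study_id, {}).get(target, 0.0)
        mu_i = p_pop * math.exp(eta)
        var_eta = 0.0
        if arm.study_id in fit.ebe_var:
            var_eta = float(fit.ebe_var[arm.study_id][re_index, re_index])
        se = mu_i * math.sqrt(max(var_eta, 0.0))
        se = max(se, 1e-6)
        cov = arm.covariates
        out.append(
            ArmParameterEstimate(
                study_id=arm.study_id,
                arm_id=arm.arm_id,
                n=arm.n,
                mu_i=mu_i,
                se_mu_i=se,
                scenario_labels={
                    "therapy_type": cov.therapy_type,
                    "drug": cov.drug,
                    "biomarker": cov.biomarker,
                    "platinum": cov.platinum,
                    "partner": cov.partner,
                },
            )
        )
    return out


def random_effects_pool(
    arms: Sequence[ArmParameterEstimate], scenario: str = "", ci_level: float = 0.90
) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooling of arm-level estimates.

    tau^2 is the usual moment estimator max(0, (Q - (k-1)) / (S1 - S2/S1))
    from the fixed-effect weights; the pooled mean uses weights
    1/(se_i^2 + tau^2).  A single arm is returned as-is with its own SE.
    """
    if not arms:
        raise ValueError(f"scenario {scenario!r} matched no arms")
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + ci_level / 2.0)
    y = np.array([a.mu_i for a in arms])
    v = np.array([a.se_mu_i ** 2 for a in arms])
    k = len(y)
    if k == 1:
        se = math.sqrt(v[0])
        return PooledEstimate(scenario, float(y[0]), se,
                              (float(y[0] - zcrit * se), float(y[0] + zcrit * se)),
                              0.0, 1)
    w = 1.0 / v
    ybar_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar_fe) ** 2))
    s1 = float(np.sum(w))
    s2 = float(np.sum(w ** 2))
    tau2 = max(0.0, (q - (k - 1)) / (s1 - s2 / s1))
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    se = math.sqrt(1.0 / float(np.sum(w_re)))
    return PooledEstimate(scenario, pooled, se,
                          (pooled - zcrit * se, pooled + zcrit * se), tau2, k)


def simulate_scenario(
    pooled: PooledEstimate,
    sigma: float,
    n_rep: int = 10000,
    time_grid=None,
    seed: int = 0,
    ci_level: float = 0.90,
) -> ScenarioSummary:
    """Monte-Carlo PFS under a pooled parameter distribution.

    Draws mu* ~ Normal(pooled, SE implied by the pooled CI) per replicate,
    evaluates the log-normal survival curve on the grid, and summarizes the
    per-time median and the (1 +/- ci_level)/2 percentiles, plus the median
    survival time exp(mu*) per replicate.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + ci_level / 2.0)
    se = (pooled.ci90_mu[1] - pooled.ci90_mu[0]) / (2.0 * zcrit)
    if time_grid is None:
        time_grid = np.arange(1.0, 48.1, 1.0)
    time_grid = np.asarray(time_grid, dtype=float)
    rng = np.random.default_rng(seed)
    mu_draws = pooled.pooled_mu + se * rng.standard_normal(n_rep)

    logt = np.log(time_grid)
    from scipy.special import ndtr

    # (n_rep, n_time) survival matrix
    z = (logt[None, :] - mu_draws[:, None]) / sigma
    surv = ndtr(-z)
    lo_q, hi_q = 50 * (1 - ci_level), 50 * (1 + ci_level)
    band = pd.DataFrame({
        "time": time_grid,
        "p_lo": np.percentile(surv, lo_q, axis=0),
        "p50": np.percentile(surv, 50, axis=0),
        "p_hi": np.percentile(surv, hi_q, axis=0),
    })
    medians = np.exp(mu_draws)  # log-normal closed form for S(t) = 0.5
    med = float(np.percentile(medians, 50))
    ci = (float(np.percentile(medians, lo_q)), float(np.percentile(medians, hi_q)))
    return ScenarioSummary(
        scenario=pooled.scenario,
        pooled=pooled,
        time_grid=time_grid,
        pfs_band=band,
        median_pfs=med,
        median_pfs_ci90=ci,
        seed=seed,
    )


def run_scenarios(
    fit: FitResult,
    corpus: Corpus,
    scenarios: dict[str, dict] | None = None,
    n_rep: int = 10000,
    seed: int = 0,
    ci_level: float = 0.90,
) -> list[ScenarioSummary]:
    """Pool and simulate every scenario; returns one summary per scenario.

    ``scenarios`` maps a label to covariate filters, e.g.
    ``{"monotherapy": {"therapy_type": "monotherapy"}}``.  By default the
    two therapy types, the three drugs and the three biomarkers (crossed
    with therapy type where arms exist) are simulated.
    """
    arms = arm_parameters(fit, corpus)
    if scenarios is None:
        scenarios = {}
        for tt in ("monotherapy", "combination"):
            scenarios[tt] = {"therapy_type": tt}
        for drug in ("olaparib", "niraparib", "rucaparib"):
            scenarios[drug] = {"drug": drug}
        for bm in ("BRCAm", "BRCAwt", "HRD_positive"):
            scenarios[bm] = {"biomarker": bm}
    sigma = fit.theta.get("sigma")
    if sigma is None:
        raise ValueError("scenario simulation requires the log-normal family")
    out = []
    for i, (label, filt) in enumerate(scenarios.items()):
        matched = [a for a in arms if a.matches(**filt)]
        if not matched:
            raise ValueError(f"scenario {label!r} matched no arms")
        pooled = random_effects_pool(matched, label, ci_level)
        out.append(
            simulate_scenario(pooled, sigma, n_rep=n_rep, seed=seed + i,
                              ci_level=ci_level)
        )
    return out
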