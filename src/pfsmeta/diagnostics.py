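"""Model diagnostics: goodness-of-fit residuals, VPC, bootstrap, sensitivity.

* :func:`gof_tables` - observation-level table with population (PRED) and
  individual (IPRED) predictions and conditional weighted residuals
  (CWRES), computed by first-order linearization of the model around the
  empirical Bayes eta with the combined residual covariance.
* :func:`vpc` - visual predictive check: percentile bands of simulated
  corpus replicates against the observations, with 95%-band coverage.
* :func:`bootstrap` - study-level nonparametric bootstrap of the fit.
* :func:`sensitivity_refit` - refit after dropping flagged (e.g.
  open-label) arms, with a side-by-side estimate table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .dataset import Arm, Corpus
from .fitting import (
    FitResult,
    ModelSpec,
    _compile,
    _cov_log_adjust,
    _study_pred,
    fit as _fit,
)

__all__ = [
    "VpcResult",
    "BootstrapResult",
    "gof_tables",
    "vpc",
    "bootstrap",
    "sensitivity_refit",
]


def _residual_sd(pred: np.ndarray, n: np.ndarray, se_stored: np.ndarray,
                 model: ModelSpec, eps_prop: float, eps_add: float) -> np.ndarray:
    if model.se_weighting == "model":
        pc = np.clip(pred, 0.5 / n, 1.0 - 0.5 / n)
        se2 = pc * (1.0 - pc) / n
    else:
        se2 = se_stored ** 2
    return np.sqrt(se2 * (pred ** 2 * eps_prop ** 2 + eps_add ** 2))


def gof_tables(fit_result: FitResult, corpus: Corpus) -> pd.DataFrame:
    """Observation-level goodness-of-fit table.

    Columns: study, arm, time, OBS, PRED (eta = 0), IPRED (eta = EBE),
    RES, CWRES.  CWRES decorrelates each study's residual vector with the
    covariance G Omega G' + V from the first-order expansion around the
    EBE, the standard conditional-estimation convention.
    """
    if not fit_result.converged:
        raise ValueError("goodness-of-fit requires a converged fit")
    model = fit_result.model
    params = fit_result.params()
    compiled = _compile(corpus, model)
    re_targets = model.re_targets
    omega = np.array([
        params.get("omega_mu", 0.0) if i == 0 else params.get("omega_sigma", 0.0)
        for i in range(len(re_targets))
    ])
    rows = []
    for study in compiled:
        adj = _cov_log_adjust(study, model, params)
        eta_hat = np.array([fit_result.ebe[study.study_id][t] for t in re_targets])
        zero = np.zeros_like(eta_hat)
        pred = _study_pred(study, model, params, zero, adj)
        ipred = _study_pred(study, model, params, eta_hat, adj)
        sd = _residual_sd(ipred, study.n_arr, study.se_w, model,
                          params["eps_prop"], params["eps_add"])
        # gradient of predictions in eta (m x d), central differences
        h = 1e-5
        G = np.empty((study.m, len(eta_hat)))
        for i in range(len(eta_hat)):
            e = np.zeros_like(eta_hat); e[i] = h
            G[:, i] = (_study_pred(study, model, params, eta_hat + e, adj)
                       - _study_pred(study, model, params, eta_hat - e, adj)) / (2 * h)
        cov = G @ np.diag(omega ** 2) @ G.T + np.diag(sd ** 2)
        mean_foce = ipred - G @ eta_hat
        L = cholesky(cov, lower=True)
        cwres = solve_triangular(L, study.obs - mean_foce, lower=True)
        for j, (arm, sl) in enumerate(study.arm_rows):
            idx = range(sl.start, sl.stop)
            for k in idx:
                rows.append({
                    "study_id": study.study_id,
                    "arm_id": arm.arm_id,
                    "time": study.t[k],
                    "OBS": study.obs[k],
                    "PRED": pred[k],
                    "IPRED": ipred[k],
                    "RES": study.obs[k] - pred[k],
                    "CWRES": cwres[k],
                })
    return pd.DataFrame(rows)


@dataclass
class VpcResult:
    """Percentile bands of simulated replicates vs the observations."""

    time_grid: np.ndarray
    table: pd.DataFrame  # study, arm, time, obs, p2.5, p50, p97.5
    coverage: float
    n_sim: int
    seed: int

    @property
    def sim_percentiles(self) -> pd.DataFrame:
        return self.table[["time", "p2.5", "p50", "p97.5"]]

    @property
    def observed_points(self) -> pd.DataFrame:
        return self.table[["time", "obs"]]


def vpc(fit_result: FitResult, corpus: Corpus, n_sim: int = 1000,
        seed: int = 0) -> VpcResult:
    """Visual predictive check against ``n_sim`` simulated corpus replicates.

    Each replicate redraws study etas and observation noise from the
    fitted model on the corpus design; percentile bands (2.5/50/97.5) are
    per (arm, time).  Percentiles use the raw (untruncated) simulated
    fractions; ``coverage`` is the share of observations inside their own
    95% band.
    """
    if not fit_result.converged:
        raise ValueError("VPC requires a converged fit")
    model = fit_result.model
    params = fit_result.params()
    compiled = _compile(corpus, model)
    re_targets = model.re_targets
    omega = np.array([
        params.get("omega_mu", 0.0) if i == 0 else params.get("omega_sigma", 0.0)
        for i in range(len(re_targets))
    ])
    rng = np.random.default_rng(seed)
    rows = []
    hits = 0
    total = 0
    for study in compiled:
        adj = _cov_log_adjust(study, model, params)
        sims = np.empty((n_sim, study.m))
        for r in range(n_sim):
            eta = rng.normal(0.0, 1.0, size=len(omega)) * omega
            pred = _study_pred(study, model, params, eta, adj)
            sd = _residual_sd(pred, study.n_arr, study.se_w, model,
                              params["eps_prop"], params["eps_add"])
            sims[r] = pred + sd * rng.standard_normal(study.m)
        lo = np.percentile(sims, 2.5, axis=0)
        mid = np.percentile(sims, 50.0, axis=0)
        hi = np.percentile(sims, 97.5, axis=0)
        inside = (study.obs >= lo) & (study.obs <= hi)
        hits += int(inside.sum())
        total += study.m
        for arm, sl in study.arm_rows:
            for k in range(sl.start, sl.stop):
                rows.append({
                    "study_id": study.study_id,
                    "arm_id": arm.arm_id,
                    "time": study.t[k],
                    "obs": study.obs[k],
                    "p2.5": lo[k],
                    "p50": mid[k],
                    "p97.5": hi[k],
                })
    table = pd.DataFrame(rows)
    return VpcResult(
        time_grid=np.unique(table["time"].to_numpy()),
        table=table,
        coverage=hits / total,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    param_medians: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    robustness_warning: bool
    seed: int
    samples: pd.DataFrame

    @property
    def success_rate(self) -> float:
        return 100.0 * self.n_converged / self.n_requested

    def report(self) -> str:
        lines = [f"{'parameter':<30}{'median':>12}{'95% CI':>26}", "-" * 68]
        for k, m in self.param_medians.items():
            lo, hi = self.ci95[k]
            lines.append(f"{k:<30}{m:>12.4g}{f'({lo:.4g}, {hi:.4g})':>26}")
        lines.append(f"success rate: {self.success_rate:.1f}%")
        return "\n".join(lines)


def bootstrap(corpus: Corpus, model: ModelSpec, n: int = 1000, seed: int = 0,
              stratify_by: str | None = None, n_starts: int = 1) -> BootstrapResult:
    """Nonparametric bootstrap with the study as the resampling unit.

    Studies are drawn with replacement to the original study count and the
    model refitted on each replicate; medians and 2.5-97.5 percentile
    intervals are computed over converged replicates.  ``stratify_by``
    optionally names a categorical covariate: studies are then resampled
    within the strata defined by whether any arm sits off that covariate's
    reference level, so sparse strata (e.g. the few combination-therapy
    studies) stay represented.  Fewer than 50% converged replicates sets
    ``robustness_warning``.
    """
    studies = corpus.studies
    if len(studies) < 3:
        raise ValueError("bootstrap requires at least 3 studies")
    ids = list(studies)
    rng = np.random.default_rng(seed)

    if stratify_by is not None:
        from .covariates import CATEGORICAL_LEVELS

        reference = CATEGORICAL_LEVELS[stratify_by][0]
        strata: dict[bool, list[str]] = {True: [], False: []}
        for sid, arms in studies.items():
            off_ref = any(a.covariates.get(stratify_by) != reference for a in arms)
            strata[off_ref].append(sid)
        groups = [g for g in strata.values() if g]
    else:
        groups = [ids]

    records = []
    for b in range(n):
        sampled: list[str] = []
        for g in groups:
            sampled.extend(rng.choice(g, size=len(g), replace=True))
        arms = []
        for j, sid in enumerate(sampled):
            for arm in studies[sid]:
                arms.append(replace(arm, study_id=f"B{j}_{sid}"))
        rep = Corpus(arms=arms, meta={"bootstrap_rep": b})
        try:
            res = _fit(rep, model, seed=seed + b + 1, n_starts=n_starts,
                       compute_se=False)
        except Exception:
            records.append({"converged": False})
            continue
        rec = {"converged": res.converged, "ofv": res.ofv}
        if res.converged:
            rec.update(res.params())
        records.append(rec)
    samples = pd.DataFrame(records)
    ok = samples[samples["converged"] == True]  # noqa: E712
    param_cols = [c for c in ok.columns if c not in ("converged", "ofv")]
    medians = {c: float(ok[c].median()) for c in param_cols}
    ci95 = {
        c: (float(np.percentile(ok[c], 2.5)), float(np.percentile(ok[c], 97.5)))
        for c in param_cols
    }
    return BootstrapResult(
        n_requested=n,
        n_converged=int(len(ok)),
        param_medians=medians,
        ci95=ci95,
        robustness_warning=len(ok) < 0.5 * n,
        seed=seed,
        samples=samples,
    )


def sensitivity_refit(corpus: Corpus, model: ModelSpec,
                      exclude_flag: str = "blinded", seed: int = 0,
                      full_fit: FitResult | None = None):
    """Refit after dropping arms whose ``exclude_flag`` covariate is False.

    With the default flag this removes all open-label arms, mirroring a
    sensitivity analysis that keeps only blinded studies.  Returns the
    refit plus a side-by-side comparison table; refuses when fewer than
    two studies remain.
    """
    kept = [a for a in corpus.arms
            if a.covariates.get(exclude_flag) in (True, None)]
    remaining_studies = {a.study_id for a in kept}
    if len(remaining_studies) < 2:
        raise ValueError(
            f"sensitivity refit needs >= 2 studies; {len(remaining_studies)} remain "
            f"after exclusion"
        )
    sub = Corpus(arms=[replace(a) for a in kept], meta=dict(corpus.meta))
    refit = _fit(sub, model, seed=seed)
    if full_fit is None:
        full_fit = _fit(corpus, model, seed=seed)
    full_p, sub_p = full_fit.params(), refit.params()
    comparison = pd.DataFrame({
        "parameter": list(full_p),
        "full": [full_p[k] for k in full_p],
        "sensitivity": [sub_p.get(k, float("nan")) for k in full_p],
    })
    return refit, comparison
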