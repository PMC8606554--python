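"""Covariate parameterization, missingness handling, and stepwise selection.

A covariate scales a population parameter multiplicatively:

* continuous:  P_pop = P_typical * exp((COV - COV_median) * theta)
* categorical: P_pop = P_typical * (1 + theta) off the reference level

Multi-level categorical covariates carry one theta per non-reference
level; the levels of one covariate are tested jointly during selection.

Selection is forward inclusion / backward elimination on the objective
function value (OFV, -2 log marginal likelihood): a candidate enters when
it drops the OFV by more than 2.71 (p < 0.1 at 1 df) and survives backward
elimination only if its removal raises the OFV by more than 3.84
(p < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import Corpus

__all__ = [
    "CovariateEffect",
    "SelectionTrace",
    "SelectionStep",
    "apply_covariate",
    "impute_missing",
    "forward_backward_select",
    "candidate_effects",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

FORWARD_THRESHOLD = 2.71   # chi-square(1) critical value at p = 0.1
BACKWARD_THRESHOLD = 3.84  # chi-square(1) critical value at p = 0.05

CONTINUOUS_COVARIATES = ("ecog0_pct", "median_age")
CATEGORICAL_LEVELS = {
    "therapy_type": ("combination", ("monotherapy",)),
    "drug": ("olaparib", ("niraparib", "rucaparib")),
    "biomarker": ("BRCAm", ("BRCAwt", "HRD_positive")),
    "platinum": ("sensitive", ("partially_resistant",)),
    "partner": ("none", ("chemotherapy", "bevacizumab", "cediranib")),
    "blinded": (True, (False,)),
}


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on a population parameter.

    For a categorical covariate ``level`` names the non-reference level
    this theta applies to and ``reference_level`` the reference; for a
    continuous covariate ``reference_level`` holds COV_median and
    ``level`` is unused.
    """

    covariate: str
    kind: str  # "categorical" | "continuous"
    target_parameter: str = "mu"
    theta_cov: float = 0.0
    reference_level: object = None
    level: object = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind: {self.kind!r}")
        if self.kind == "categorical" and self.theta_cov <= -1:
            raise ValueError("categorical theta_cov must be > -1")

    @property
    def key(self) -> str:
        """Flat parameter name used in fit results and config files."""
        if self.kind == "categorical":
            return f"theta_{self.covariate}_{self.level}"
        return f"theta_{self.covariate}"

    def design_value(self, profile) -> float:
        """The per-arm regressor: 0/1 indicator or centered covariate."""
        value = profile.get(self.covariate)
        if self.kind == "categorical":
            return 1.0 if value == self.level else 0.0
        if value is None:
            raise ValueError(
                f"covariate {self.covariate!r} unresolved (missing value); "
                "impute before fitting"
            )
        return float(value) - float(self.reference_level)


def apply_covariate(p_typical: float, profile, effects: Sequence[CovariateEffect]) -> float:
    """Population parameter after all covariate terms, composed multiplicatively."""
    log_p = math.log(p_typical)
    for eff in effects:
        x = eff.design_value(profile)
        if eff.kind == "categorical":
            log_p += x * math.log1p(eff.theta_cov)
        else:
            log_p += x * eff.theta_cov
    return math.exp(log_p)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    idx = int(np.searchsorted(cum, half))
    if math.isclose(cum[idx], half, rel_tol=0, abs_tol=1e-12) and idx + 1 < len(v):
        return 0.5 * (v[idx] + v[idx + 1])
    return float(v[idx])


@dataclass
class ImputationReport:
    covariate: str
    missing_patients: int
    total_patients: int
    imputed_value: float | None
    untestable: bool

    @property
    def missing_fraction(self) -> float:
        return self.missing_patients / self.total_patients


def impute_missing(corpus: Corpus, covariate: str) -> tuple[Corpus, ImputationReport]:
    """Fill blanks in a continuous covariate by the patient-weighted median.

    Blanks are always imputed when any value is observed; if more than 30%
    of patients (weighting arms by n) lacked the value, the covariate is
    additionally flagged untestable, which excludes it from the stepwise
    candidate set.  A covariate with no observed values at all cannot be
    imputed and is returned unchanged (untestable).
    """
    if covariate not in CONTINUOUS_COVARIATES:
        raise ValueError(f"{covariate!r} is not a declared continuous covariate")
    values, weights, missing_n = [], [], 0
    for arm in corpus.arms:
        v = arm.covariates.get(covariate)
        if v is None:
            missing_n += arm.n
        else:
            values.append(float(v))
            weights.append(arm.n)
    total = corpus.n_patients
    untestable = missing_n / total > 0.30
    if not values:
        report = ImputationReport(covariate, missing_n, total, None, True)
        return corpus, report
    med = _weighted_median(np.array(values), np.array(weights, dtype=float))
    new_arms = []
    for arm in corpus.arms:
        if arm.covariates.get(covariate) is None:
            new_arms.append(
                replace(arm, covariates=replace(arm.covariates, **{covariate: med}))
            )
        else:
            new_arms.append(arm)
    report = ImputationReport(covariate, missing_n, total, med, untestable)
    out = Corpus(arms=new_arms, meta=dict(corpus.meta))
    return out, report


def candidate_effects(corpus: Corpus, covariate: str, target: str = "mu") -> list[CovariateEffect]:
    """Build the effect block (one theta per non-reference level) for a covariate."""
    if covariate in CONTINUOUS_COVARIATES:
        vals = np.array(
            [a.covariates.get(covariate) for a in corpus.arms if a.covariates.get(covariate) is not None],
            dtype=float,
        )
        if vals.size == 0:
            raise ValueError(f"covariate {covariate!r} has no observed values")
        w = np.array(
            [a.n for a in corpus.arms if a.covariates.get(covariate) is not None],
            dtype=float,
        )
        med = _weighted_median(vals, w)
        return [
            CovariateEffect(
                covariate=covariate, kind="continuous",
                target_parameter=target, reference_level=med,
            )
        ]
    if covariate not in CATEGORICAL_LEVELS:
        raise ValueError(f"unknown covariate {covariate!r}")
    reference, others = CATEGORICAL_LEVELS[covariate]
    present = {a.covariates.get(covariate) for a in corpus.arms}
    return [
        CovariateEffect(
            covariate=covariate, kind="categorical",
            target_parameter=target, reference_level=reference, level=lvl,
        )
        for lvl in others
        if lvl in present
    ]


@dataclass
class SelectionStep:
    direction: str  # "forward" | "backward"
    candidate: str
    delta_ofv: float
    accepted: bool
    note: str = ""


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    final_model: list[str] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "direction": s.direction,
                "candidate": s.candidate,
                "delta_ofv": s.delta_ofv,
                "accepted": s.accepted,
                "note": s.note,
            }
            for s in self.steps
        ]


def forward_backward_select(
    corpus: Corpus,
    base_model,
    candidates: Sequence[str],
    seed: int = 0,
    target: str = "mu",
):
    """Stepwise covariate selection by OFV thresholds.

    Forward phase: refit with each remaining candidate added singly; the
    largest OFV drop wins if it exceeds 2.71 (ties under 1e-6 broken by
    declaration order).  Backward phase: covariates whose single removal
    from the full model fails to raise the OFV by more than 3.84 are
    dropped, iterating to stability.  Candidates whose fit does not
    converge are skipped that step and recorded in the trace.

    Returns (trace, final FitResult).
    """
    from .fitting import fit  # deferred: fitting imports this module

    # impute continuous candidates up front; drop untestable ones
    trace = SelectionTrace()
    usable: list[str] = []
    for cov in candidates:
        if cov in CONTINUOUS_COVARIATES:
            corpus, report = impute_missing(corpus, cov)
            if report.untestable:
                trace.steps.append(
                    SelectionStep("forward", cov, float("nan"), False,
                                  "excluded: >30% of patients missing")
                )
                continue
        usable.append(cov)

    blocks = {cov: candidate_effects(corpus, cov, target) for cov in usable}
    included: list[str] = []

    def fit_with(covs: list[str], sub_seed: int):
        effects = [e for c in covs for e in blocks[c]]
        model = replace(base_model, covariate_effects=list(base_model.covariate_effects) + effects)
        return fit(corpus, model, seed=sub_seed, compute_se=False)

    base_fit = fit_with([], seed)
    if not base_fit.converged:
        raise RuntimeError("base model failed to converge; cannot run selection")
    current_fit, current_ofv = base_fit, base_fit.ofv

    # ---- forward inclusion ----
    remaining = list(usable)
    step_seed = seed
    while remaining:
        results = []
        for cov in remaining:
            step_seed += 1
            try:
                f = fit_with(included + [cov], step_seed)
            except Exception as exc:  # pragma: no cover - defensive
                trace.steps.append(SelectionStep("forward", cov, float("nan"), False, f"fit error: {exc}"))
                continue
            if not f.converged:
                trace.steps.append(SelectionStep("forward", cov, float("nan"), False, "did not converge"))
                continue
            results.append((cov, f, current_ofv - f.ofv))
        if not results:
            break
        best_drop = max(r[2] for r in results)
        # declaration order breaks near-ties
        winner = next(r for r in results if r[2] > best_drop - 1e-6)
        for cov, f, drop in results:
            if cov is winner[0]:
                continue
            trace.steps.append(SelectionStep("forward", cov, drop, False))
        cov, f, drop = winner
        if drop > FORWARD_THRESHOLD:
            trace.steps.append(SelectionStep("forward", cov, drop, True))
            included.append(cov)
            remaining.remove(cov)
            current_fit, current_ofv = f, f.ofv
        else:
            trace.steps.append(SelectionStep("forward", cov, drop, False))
            break

    # ---- backward elimination ----
    changed = True
    while changed and included:
        changed = False
        for cov in list(included):
            step_seed += 1
            reduced = [c for c in included if c != cov]
            try:
                f = fit_with(reduced, step_seed)
            except Exception as exc:  # pragma: no cover - defensive
                trace.steps.append(SelectionStep("backward", cov, float("nan"), True, f"fit error: {exc}"))
                continue
            if not f.converged:
                trace.steps.append(SelectionStep("backward", cov, float("nan"), True, "removal fit did not converge"))
                continue
            rise = f.ofv - current_ofv
            if rise > BACKWARD_THRESHOLD:
                trace.steps.append(SelectionStep("backward", cov, rise, True, "retained"))
            else:
                trace.steps.append(SelectionStep("backward", cov, rise, False, "removed"))
                included.remove(cov)
                current_fit, current_ofv = f, f.ofv
                changed = True
                break

    trace.final_model = list(included)
    return trace, current_fit
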