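"""Reusable simulation experiments over the reference synthetic design.

These drive the repeated generate-and-refit studies used by the analysis
scripts and the acceptance checks: parameter recovery at the reference
generating truth, hazard-family discrimination by OFV, and stepwise
covariate-selection operating characteristics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import forward_backward_select
from .fitting import FAMILY_PARAMS, ModelSpec, fit
from .simulate import default_truth, generate_corpus

__all__ = [
    "REFERENCE_TRUTH_VALUES",
    "recovery_experiment",
    "family_comparison",
    "selection_experiment",
]

# the generating truth of default_truth(), keyed by estimate name
REFERENCE_TRUTH_VALUES = {
    "mu": 2.96,
    "sigma": 0.999,
    "theta_therapy_type_monotherapy": -0.215,
    "omega_mu": 0.159,
    "omega_sigma": 0.142,
    "eps_add": 1.241,
    "eps_prop": 0.429,
}


def recovery_experiment(seeds, compute_se: bool = False) -> pd.DataFrame:
    """Generate one corpus per seed at the reference truth and refit it.

    Returns one row per replicate with every estimate plus convergence;
    medians across rows are the recovery summaries.
    """
    truth = default_truth()
    model = ModelSpec(covariate_effects=list(truth.covariate_effects))
    rows = []
    for seed in seeds:
        corpus, _ = generate_corpus(truth, seed=seed)
        res = fit(corpus, model, seed=seed, compute_se=compute_se)
        rows.append({"seed": seed, "converged": res.converged, "ofv": res.ofv,
                     **res.params()})
    return pd.DataFrame(rows)


def recovery_medians(table: pd.DataFrame) -> dict[str, float]:
    ok = table[table["converged"]]
    return {k: float(ok[k].median()) for k in REFERENCE_TRUTH_VALUES}


def family_comparison(seeds) -> pd.DataFrame:
    """Fit all four hazard families to corpora drawn from the log-normal truth.

    Returns one row per (seed, family) with the OFV, for model
    discrimination by OFV minimization.
    """
    from dataclasses import replace

    truth = default_truth()
    rows = []
    for seed in seeds:
        corpus, _ = generate_corpus(truth, seed=seed)
        for family in FAMILY_PARAMS:
            # the therapy covariate scales the family's location-like
            # parameter: mu for the log-normal, lambda0 otherwise
            target = "mu" if family == "lognormal" else "lambda0"
            effects = [replace(e, target_parameter=target)
                       for e in truth.covariate_effects]
            model = ModelSpec(family=family, covariate_effects=effects)
            res = fit(corpus, model, seed=seed, compute_se=False)
            rows.append({"seed": seed, "family": family, "ofv": res.ofv,
                         "converged": res.converged})
    return pd.DataFrame(rows)


def selection_experiment(seeds, candidates=("therapy_type", "median_age")) -> pd.DataFrame:
    """Run forward/backward selection on one corpus per seed.

    The default candidate list pairs the generating therapy-type effect
    with a covariate the generator leaves null (median age), so the table
    doubles as a power / false-inclusion summary: one row per seed with an
    inclusion flag per candidate.
    """
    truth = default_truth()
    base = ModelSpec()
    rows = []
    for seed in seeds:
        corpus, _ = generate_corpus(truth, seed=seed)
        trace, final = forward_backward_select(corpus, base, list(candidates),
                                               seed=seed)
        row = {"seed": seed, "final_ofv": final.ofv}
        for cand in candidates:
            row[f"included_{cand}"] = cand in trace.final_model
        rows.append(row)
    return pd.DataFrame(rows)
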