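#!/usr/bin/env python
"""Diagnostics of the fitted final model: GOF, VPC, bootstrap, sensitivity.

Writes results/gof.csv, results/vpc.csv, results/bootstrap.json and
results/sensitivity.csv.  The bootstrap here runs 200 study-level
replicates (stratified so the combination-therapy studies stay
represented); the VPC uses 1,000 simulated corpus replicates.
"""

import json
from pathlib import Path

from pfsmeta.dataset import read_corpus
from pfsmeta.diagnostics import bootstrap, gof_tables, sensitivity_refit, vpc
from pfsmeta.fitting import FitResult

SEED = 1
N_BOOT = 200
N_SIM = 1000
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    corpus = read_corpus(OUT / "corpus.csv")
    fit_result = FitResult.from_json(str(OUT / "fit.json"))

    gof = gof_tables(fit_result, corpus)
    gof.to_csv(OUT / "gof.csv", index=False)
    print(f"GOF: CWRES mean {gof['CWRES'].mean():+.3f}, "
          f"sd {gof['CWRES'].std():.3f}, max |CWRES| {gof['CWRES'].abs().max():.2f}")

    v = vpc(fit_result, corpus, n_sim=N_SIM, seed=SEED)
    v.table.to_csv(OUT / "vpc.csv", index=False)
    print(f"VPC: 95%-band coverage {v.coverage:.3f} over {v.n_sim} replicates")

    boot = bootstrap(corpus, fit_result.model, n=N_BOOT, seed=SEED,
                     stratify_by="therapy_type")
    with open(OUT / "bootstrap.json", "w") as fh:
        json.dump({"n_requested": boot.n_requested,
                   "n_converged": boot.n_converged,
                   "success_rate_pct": boot.success_rate,
                   "param_medians": boot.param_medians,
                   "ci95": boot.ci95}, fh, indent=2)
    print(f"Bootstrap: success rate {boot.success_rate:.1f}%")
    print(boot.report())

    refit, comparison = sensitivity_refit(corpus, fit_result.model,
                                          seed=SEED, full_fit=fit_result)
    comparison.to_csv(OUT / "sensitivity.csv", index=False)
    print("\nSensitivity (open-label studies removed):")
    print(comparison.to_string(index=False))


if __name__ == "__main__":
    main()
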