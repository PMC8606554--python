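#!/usr/bin/env python
"""Stepwise covariate selection on the reference corpus.

Forward inclusion (dOFV > 2.71) then backward elimination (retain only if
removal raises OFV by > 3.84), with the generating therapy-type effect
among the candidates next to covariates the generator leaves null.
Writes results/selection.json and the selected model's parameter table.
"""

import json
from pathlib import Path

from pfsmeta.covariates import forward_backward_select
from pfsmeta.dataset import read_corpus
from pfsmeta.fitting import ModelSpec

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"
CANDIDATES = ["therapy_type", "platinum", "median_age"]


def main() -> None:
    corpus = read_corpus(OUT / "corpus.csv")
    trace, final = forward_backward_select(corpus, ModelSpec(), CANDIDATES,
                                           seed=SEED)
    with open(OUT / "selection.json", "w") as fh:
        json.dump({"steps": trace.to_records(),
                   "final_model": trace.final_model}, fh, indent=2)
    for s in trace.steps:
        print(f"{s.direction:<9}{s.candidate:<14}dOFV={s.delta_ofv:8.3f}  "
              f"{'accepted' if s.accepted else 'rejected'} {s.note}")
    print(f"\nfinal covariates: {trace.final_model}")
    print(f"final OFV: {final.ofv:.3f}")


if __name__ == "__main__":
    main()
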