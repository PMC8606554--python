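import numpy as np
import pytest

from pfsmeta.fitting import ModelSpec, fit
from pfsmeta.simulate import (
    ArmDesign,
    GeneratingTruth,
    default_truth,
    generate_corpus,
    _profile,
)


@pytest.fixture(scope="session")
def ref_truth():
    """The reference generating truth (8 studies / 12 arms / 1,169 patients)."""
    return default_truth()


@pytest.fixture(scope="session")
def ref_corpus(ref_truth):
    corpus, record = generate_corpus(ref_truth, seed=1)
    return corpus, record


@pytest.fixture(scope="session")
def ref_fit(ref_truth, ref_corpus):
    """One converged fit of the reference corpus, shared across tests."""
    corpus, _ = ref_corpus
    model = ModelSpec(covariate_effects=list(ref_truth.covariate_effects))
    result = fit(corpus, model, seed=1)
    assert result.converged
    return result


def toy_truth(n_studies=3, n=80, times=(4.0, 10.0, 18.0, 30.0), **kw):
    """Small single-arm-per-study monotherapy truth for cheap tests."""
    design = [
        ArmDesign(f"S{i}", "A", n, _profile("monotherapy", "olaparib", "BRCAm"))
        for i in range(n_studies)
    ]
    defaults = dict(design=design, time_grid=tuple(times))
    defaults.update(kw)
    return GeneratingTruth(**defaults)


@pytest.fixture
def toy_corpus():
    corpus, record = generate_corpus(toy_truth(), seed=11)
    return corpus, record
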