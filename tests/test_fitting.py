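import itertools
import math

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import ndtr

from pfsmeta.covariates import CovariateEffect
from pfsmeta.dataset import Corpus
from pfsmeta.fitting import (
    ModelSpec,
    arm_prediction,
    empirical_bayes,
    fit,
    marginal_ofv,
    residual_se,
)
from pfsmeta.simulate import generate_corpus
from .conftest import toy_truth

REF_PARAMS = dict(mu=2.96, sigma=0.999, omega_mu=0.159, omega_sigma=0.142,
                  eps_prop=0.429, eps_add=1.241)


class TestResidualSe:
    @pytest.mark.parametrize(
        "p,n,expected",
        [(0.5, 100, 0.05), (1.0, 50, 0.0), (0.0, 7, 0.0),
         (0.9, 90, 0.0316228)],
    )
    def test_binomial_formula(self, p, n, expected):
        assert residual_se(p, n) == pytest.approx(expected, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            residual_se(0.5, 0)
        with pytest.raises(ValueError):
            residual_se(1.5, 10)


class TestArmPrediction:
    def test_population_prediction_without_eta(self):
        from pfsmeta.hazards import HazardParams, survival

        times = [3.0, 9.0, 24.0]
        pred = arm_prediction({"mu": 2.96, "sigma": 0.999}, {}, None, times)
        hp = HazardParams(family="lognormal", mu=2.96, sigma=0.999)
        assert np.allclose(pred, survival(hp, np.array(times)), atol=1e-14)

    def test_eta_scales_mu_multiplicatively(self):
        # eta = ln(1.1) multiplies mu itself, so the individual median time
        # is exp(2.96 * 1.1), not 1.1 * exp(2.96)
        eta = math.log(1.1)
        mu_i = 2.96 * 1.1
        t_med = math.exp(mu_i)
        pred = arm_prediction({"mu": 2.96, "sigma": 0.999}, {"mu": eta}, None,
                              [t_med])
        assert pred[0] == pytest.approx(0.5, abs=1e-12)

    def test_output_monotone_non_increasing(self):
        times = np.linspace(1.0, 40.0, 25)
        pred = arm_prediction({"mu": 2.4, "sigma": 0.8}, {"mu": 0.05}, None, times)
        assert np.all(np.diff(pred) <= 0)

    def test_covariate_adjustment_applied(self):
        eff = CovariateEffect(covariate="therapy_type", kind="categorical",
                              target_parameter="mu", reference_level="combination",
                              level="monotherapy")
        model = ModelSpec(covariate_effects=[eff])
        from pfsmeta.dataset import CovariateProfile

        prof = CovariateProfile(therapy_type="monotherapy", drug="olaparib",
                                biomarker="BRCAm")
        theta = {"mu": 2.96, "sigma": 0.999, eff.key: -0.215}
        t_med = math.exp(2.96 * (1 - 0.215))
        pred = arm_prediction(theta, {}, prof, [t_med], model=model)
        assert pred[0] == pytest.approx(0.5, abs=1e-12)


def direct_eta_zero_ofv(corpus: Corpus, params: dict) -> float:
    """Oracle: closed-form weighted Gaussian -2 log likelihood at eta = 0,
    computed from scratch with textbook formulas (model-based SE weights)."""
    total = 0.0
    for arm in corpus.arms:
        z = (np.log(arm.times) - params["mu"]) / params["sigma"]
        pred = ndtr(-z)
        pc = np.clip(pred, 0.5 / arm.n, 1 - 0.5 / arm.n)
        se2 = pc * (1 - pc) / arm.n
        var = se2 * (pred ** 2 * params["eps_prop"] ** 2 + params["eps_add"] ** 2)
        r = arm.fractions - pred
        total += float(np.sum(r * r / var + np.log(2 * np.pi * var)))
    return total


def agq_ofv(corpus, model, params, nodes=9):
    """Oracle: adaptive Gauss-Hermite marginal -2 log likelihood.

    Centers a tensor-product Gauss-Hermite rule at each study's
    conditional mode with the local curvature as the scale.
    """
    from pfsmeta.fitting import (
        _compile,
        _cov_log_adjust,
        _neg_log_joint,
        _newton_mode,
    )

    compiled = _compile(corpus, model)
    x, w = hermegauss(nodes)
    total = 0.0
    for st in compiled:
        omega = np.array([params.get("omega_mu", 0.0),
                          params.get("omega_sigma", 0.0)])[: len(model.re_targets)]
        active = omega > 0
        d = int(active.sum())
        adj = _cov_log_adjust(st, model, params)
        g = _neg_log_joint(st, model, params, adj, omega, active,
                           params.get("eps_prop", 0.0) ** 2,
                           params.get("eps_add", 0.0) ** 2)
        if d == 0:
            total += 2 * g(np.zeros(0))
            continue
        mode, gmin, hess = _newton_mode(g, np.zeros(d))
        C = np.linalg.cholesky(np.linalg.inv(hess))
        acc = 0.0
        for idx in itertools.product(range(nodes), repeat=d):
            z = np.array([x[i] for i in idx])
            wt = np.prod([w[i] for i in idx])
            acc += wt * math.exp(-(g(mode + C @ z) - gmin) + 0.5 * float(z @ z))
        total += -2 * (-gmin + math.log(acc) + float(np.sum(np.log(np.diag(C)))))
    return total


class TestMarginalOfv:
    def test_zero_omega_equals_direct_gaussian(self, toy_corpus):
        corpus, _ = toy_corpus
        params = dict(REF_PARAMS, omega_mu=0.0, omega_sigma=0.0)
        got = marginal_ofv(corpus, ModelSpec(), params)
        assert got == pytest.approx(direct_eta_zero_ofv(corpus, params), abs=1e-6)

    def test_discrepancy_increases_ofv(self):
        corpus, _ = generate_corpus(
            toy_truth(n_studies=2, times=(6.0,), omega_mu=0.0, omega_sigma=0.0,
                      eps_prop=0.0, eps_add=0.0),
            seed=0,
        )
        params = dict(REF_PARAMS, omega_mu=0.0, omega_sigma=0.0)
        base = marginal_ofv(corpus, ModelSpec(), params)
        # perturb one observation away from its prediction
        corpus.arms[0].observations[0].obs_fraction += 0.02
        assert marginal_ofv(corpus, ModelSpec(), params) > base

    def test_agrees_with_gauss_hermite_oracle_on_toy_corpora(self):
        model = ModelSpec()
        for seed in (1, 2, 3):
            corpus, _ = generate_corpus(toy_truth(), seed=seed)
            lap = marginal_ofv(corpus, model, REF_PARAMS)
            agq = agq_ofv(corpus, model, REF_PARAMS)
            assert lap == pytest.approx(agq, abs=0.1)

    def test_invariant_to_study_relabeling_and_order(self, toy_corpus):
        corpus, _ = toy_corpus
        base = marginal_ofv(corpus, ModelSpec(), REF_PARAMS)
        reordered = Corpus(arms=list(reversed(corpus.arms)))
        assert marginal_ofv(reordered, ModelSpec(), REF_PARAMS) == pytest.approx(
            base, abs=1e-9
        )


class TestFit:
    def test_noiseless_corpus_recovers_parameters(self):
        truth = toy_truth(n_studies=3, n=200,
                          times=(3.0, 6.0, 9.0, 12.0, 18.0, 24.0, 30.0),
                          omega_mu=0.0, omega_sigma=0.0,
                          eps_prop=0.0, eps_add=0.0)
        corpus, _ = generate_corpus(truth, seed=5)
        res = fit(corpus, ModelSpec(), seed=5)
        assert res.theta["mu"] == pytest.approx(truth.mu, abs=1e-3)
        assert res.theta["sigma"] == pytest.approx(truth.sigma, abs=1e-3)

    def test_single_study_rejected(self):
        corpus, _ = generate_corpus(toy_truth(n_studies=1), seed=2)
        with pytest.raises(ValueError):
            fit(corpus, ModelSpec())

    def test_fit_reports_shape(self, ref_fit, ref_corpus):
        corpus, _ = ref_corpus
        assert ref_fit.converged
        assert ref_fit.n_studies == len(corpus.studies)
        assert set(ref_fit.ebe) == set(corpus.studies)
        for etas in ref_fit.ebe.values():
            assert set(etas) == {"mu", "sigma"}
        assert np.isfinite(ref_fit.ofv)
        text = ref_fit.report()
        assert "OFV" in text and "mu" in text

    def test_serialization_round_trip(self, ref_fit, tmp_path):
        path = tmp_path / "fit.json"
        ref_fit.to_json(path)
        from pfsmeta.fitting import FitResult

        back = FitResult.from_json(str(path))
        assert back.theta == pytest.approx(ref_fit.theta)
        assert back.ofv == pytest.approx(ref_fit.ofv)
        assert back.model.covariate_effects == ref_fit.model.covariate_effects
        assert back.ebe == ref_fit.ebe


class TestEmpiricalBayes:
    def test_zero_eta_data_gives_near_zero_ebe(self):
        truth = toy_truth(n_studies=3, n=500,
                          times=(3.0, 6.0, 12.0, 18.0, 24.0, 30.0),
                          omega_mu=0.0, omega_sigma=0.0,
                          eps_prop=1e-6, eps_add=1e-5)
        corpus, _ = generate_corpus(truth, seed=3)
        model = ModelSpec()
        params = dict(mu=truth.mu, sigma=truth.sigma, omega_mu=0.05,
                      omega_sigma=0.05, eps_prop=1e-6, eps_add=1e-5)
        from pfsmeta.fitting import _compile, _ebe_compiled

        ebe, _ = _ebe_compiled(_compile(corpus, model), model, params)
        for etas in ebe.values():
            assert abs(etas["mu"]) < 1e-3
            assert abs(etas["sigma"]) < 1e-3

    def test_ebes_shrink_toward_zero(self):
        # sample variance of EBEs must not exceed the generating omega^2
        truth = toy_truth(n_studies=16, n=120,
                          times=tuple(np.arange(3.0, 36.1, 3.0)))
        corpus, record = generate_corpus(truth, seed=9)
        model = ModelSpec()
        params = dict(REF_PARAMS)
        from pfsmeta.fitting import _compile, _ebe_compiled

        ebe, _ = _ebe_compiled(_compile(corpus, model), model, params)
        est = np.array([ebe[s]["mu"] for s in ebe])
        true_eta = np.array([record["eta"][s]["mu"] for s in ebe])
        # conditional modes shrink toward zero: their spread stays below
        # the prior variance omega^2 (the realized etas need not)
        assert np.var(est) <= truth.omega_mu ** 2
        # and each mode sits between zero and a neighborhood of its eta
        corr = np.corrcoef(est, true_eta)[0, 1]
        assert corr > 0.5

    def test_requires_converged_fit(self, ref_fit, ref_corpus):
        corpus, _ = ref_corpus
        ebe = empirical_bayes(ref_fit, corpus)
        assert ebe == ref_fit.ebe
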