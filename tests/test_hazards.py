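import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import lognorm

from pfsmeta.hazards import HazardParams, hazard, median_survival_time, survival


def lognormal_params(mu=2.96, sigma=0.999):
    return HazardParams(family="lognormal", mu=mu, sigma=sigma)


class TestHazard:
    def test_exponential_hazard_is_constant(self):
        p = HazardParams(family="exponential", lambda0=0.1)
        assert hazard(p, 7.0) == pytest.approx(0.1)
        assert np.allclose(hazard(p, np.array([1.0, 5.0, 30.0])), 0.1)

    def test_gompertz_beta_zero_reduces_to_exponential(self):
        p = HazardParams(family="gompertz", lambda0=0.1, beta=0.0)
        for t in (0.5, 7.0, 33.0):
            assert hazard(p, t) == pytest.approx(0.1)

    def test_weibull_form_is_power_law(self):
        p = HazardParams(family="weibull_form", lambda0=0.05, beta=0.5)
        assert hazard(p, 4.0) == pytest.approx(0.05 * 4.0 ** 0.5, rel=1e-12)

    def test_lognormal_hazard_matches_density_ratio_oracle(self):
        # oracle: textbook log-normal pdf / sf with an independent routine
        mu, sigma, t = 2.96, 0.999, 19.2980
        p = lognormal_params(mu, sigma)
        dist = lognorm(s=sigma, scale=math.exp(mu))
        expected = dist.pdf(t) / dist.sf(t)
        assert hazard(p, t) == pytest.approx(expected, abs=1e-10)

    def test_lognormal_hazard_stable_in_deep_tail(self):
        # survival ~ 1e-40 here; the complementary form must not overflow
        p = lognormal_params(0.5, 0.2)
        h = hazard(p, 60.0)
        assert np.isfinite(h) and h > 0

    def test_nonpositive_time_rejected(self):
        p = lognormal_params()
        with pytest.raises(ValueError):
            hazard(p, 0.0)


class TestSurvival:
    def test_exponential_closed_form(self):
        p = HazardParams(family="exponential", lambda0=0.1)
        assert survival(p, 10.0) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_lognormal_median_point(self):
        p = lognormal_params()
        assert survival(p, math.exp(2.96)) == pytest.approx(0.5, abs=1e-12)

    def test_weibull_closed_form(self):
        p = HazardParams(family="weibull_form", lambda0=0.05, beta=0.5)
        assert survival(p, 4.0) == pytest.approx(math.exp(-0.05 * 4.0 ** 1.5 / 1.5), rel=1e-12)

    def test_survival_at_zero_is_one_for_every_family(self):
        for p in [
            HazardParams(family="exponential", lambda0=0.2),
            HazardParams(family="gompertz", lambda0=0.1, beta=0.05),
            HazardParams(family="weibull_form", lambda0=0.05, beta=0.5),
            lognormal_params(),
        ]:
            assert survival(p, 0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival(lognormal_params(), -1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        params = _random_params(rng)
        t = np.sort(rng.uniform(0.01, 60.0, size=50))
        s = np.array([float(survival(params, ti)) for ti in t])
        assert np.all(np.diff(s) <= 1e-15)

    @pytest.mark.parametrize("seed", range(8))
    def test_closed_form_equals_hazard_quadrature(self, seed):
        # oracle: S(t) = exp(-integral of h) by adaptive quadrature
        rng = np.random.default_rng(100 + seed)
        params = _random_params(rng)
        t = float(rng.uniform(0.5, 40.0))
        integral, err = quad(lambda u: float(hazard(params, u)), 1e-12, t,
                             limit=200)
        assert float(survival(params, t)) == pytest.approx(
            math.exp(-integral), abs=1e-8
        )

    def test_gompertz_series_branch_continuous(self):
        # oracle: exact cumulative hazard lam*expm1(b t)/b, stable via expm1
        lam, t = 0.08, 20.0
        for b in (1e-9, 1e-10):
            s_series = survival(HazardParams(family="gompertz", lambda0=lam, beta=b), t)
            s_exact = math.exp(-lam * math.expm1(b * t) / b)
            assert s_series == pytest.approx(s_exact, rel=1e-12)
        # and the beta -> 0 limit agrees with the exponential family
        s0 = survival(HazardParams(family="gompertz", lambda0=lam, beta=1e-12), t)
        s_exp = survival(HazardParams(family="exponential", lambda0=lam), t)
        assert s0 == pytest.approx(s_exp, rel=1e-9)


def _random_params(rng):
    family = rng.choice(["exponential", "gompertz", "weibull_form", "lognormal"])
    if family == "exponential":
        return HazardParams(family=family, lambda0=rng.uniform(0.01, 0.3))
    if family == "gompertz":
        return HazardParams(family=family, lambda0=rng.uniform(0.01, 0.2),
                            beta=rng.uniform(-0.03, 0.08))
    if family == "weibull_form":
        return HazardParams(family=family, lambda0=rng.uniform(0.01, 0.2),
                            beta=rng.uniform(-0.8, 1.5))
    return HazardParams(family="lognormal", mu=rng.uniform(1.0, 3.5),
                        sigma=rng.uniform(0.3, 1.5))


class TestMedianSurvivalTime:
    def test_lognormal_closed_form(self):
        assert median_survival_time(lognormal_params(2.96, 0.999)) == pytest.approx(
            math.exp(2.96), rel=1e-12
        )

    def test_lognormal_after_monotherapy_scaling(self):
        # mu scaled by (1 - 0.215): median drops from 19.30 to 10.21 months
        mu = 2.96 * (1 - 0.215)
        assert median_survival_time(lognormal_params(mu, 0.999)) == pytest.approx(
            10.212, abs=5e-3
        )

    def test_lognormal_median_independent_of_sigma(self):
        m1 = median_survival_time(lognormal_params(2.0, 0.3))
        m2 = median_survival_time(lognormal_params(2.0, 1.4))
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_exponential_half_life(self):
        p = HazardParams(family="exponential", lambda0=math.log(2) / 12.0)
        assert median_survival_time(p) == pytest.approx(12.0, rel=1e-12)

    @pytest.mark.parametrize(
        "params",
        [
            HazardParams(family="gompertz", lambda0=0.05, beta=0.06),
            HazardParams(family="gompertz", lambda0=0.12, beta=-0.02),
            HazardParams(family="weibull_form", lambda0=0.02, beta=0.8),
        ],
    )
    def test_median_solves_survival_half(self, params):
        t50 = median_survival_time(params)
        assert abs(float(survival(params, t50)) - 0.5) <= 1e-10

    def test_gompertz_plateau_above_half_raises(self):
        # hazard decays so fast that S(inf) = exp(-lambda0/|beta|) > 0.5
        with pytest.raises(ValueError):
            median_survival_time(
                HazardParams(family="gompertz", lambda0=0.01, beta=-0.5)
            )


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="exponential", lambda0=-0.1),
            dict(family="lognormal", mu=2.0, sigma=0.0),
            dict(family="weibull_form", lambda0=0.1, beta=-1.0),
            dict(family="gompertz", lambda0=0.1),
            dict(family="nope", lambda0=0.1),
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HazardParams(**kwargs)
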