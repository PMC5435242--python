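import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import kstest

import conncrit as cc
from conncrit.errors import ConfigurationError, ParameterError

from conftest import POWERLAW_REF, RESTRICTED_REF, TRUNCATED_REF


class TestRestrictedPowerLaw:
    def test_gamma_zero_is_uniform(self):
        m = cc.RestrictedPowerLaw(gamma=0.0, x_min=1.0, x_max=4.0)
        x = np.linspace(1.0, 4.0, 7)
        assert np.allclose(m.pdf(x), 1.0 / 3.0)
        assert m.mean() == pytest.approx(2.5)

    def test_pointwise_density_and_boundary(self):
        m = cc.RestrictedPowerLaw(gamma=1.0, x_min=0.0, x_max=2.0)
        assert m.pdf(1.0) == pytest.approx(0.5)
        assert quad(m.pdf, 0.0, 2.0)[0] == pytest.approx(1.0, abs=1e-10)
        assert m.pdf(2.0) == 0.0  # density vanishes at the upper bound for gamma>0
        assert m.pdf(2.5) == 0.0 and m.pdf(-0.5) == 0.0

    def test_cdf_endpoints_and_analytic_value(self):
        m = cc.RestrictedPowerLaw(gamma=1.0, x_min=0.0, x_max=2.0)
        assert m.cdf(0.0) == 0.0
        assert m.cdf(2.0) == 1.0
        assert m.cdf(1.0) == pytest.approx(0.75)
        assert m.icdf(0.75) == pytest.approx(1.0)

    @given(
        gamma=st.floats(-0.9, 6.0),
        x_min=st.floats(0.01, 5.0),
        width=st.floats(0.1, 50.0),
        u=st.floats(0.0, 1.0),
    )
    def test_icdf_cdf_roundtrip(self, gamma, x_min, width, u):
        m = cc.RestrictedPowerLaw(gamma=gamma, x_min=x_min, x_max=x_min + width)
        x = m.icdf(u)
        assert x_min <= x <= m.x_max
        assert m.cdf(x) == pytest.approx(u, abs=1e-10)

    def test_mean_matches_quadrature(self, rng):
        m = cc.RestrictedPowerLaw(**RESTRICTED_REF)
        assert m.mean() == pytest.approx(8.355, abs=1e-3)
        for _ in range(10):
            g = rng.uniform(-0.8, 5.0)
            lo = rng.uniform(0.1, 2.0)
            hi = lo + rng.uniform(0.5, 30.0)
            mm = cc.RestrictedPowerLaw(gamma=g, x_min=lo, x_max=hi)
            num = quad(lambda x: x * mm.pdf(x), lo, hi)[0]
            assert mm.mean() == pytest.approx(num, abs=1e-8)

    def test_flat_limit_as_xmax_grows(self):
        # with x_max -> inf at fixed offsets above x_min the density flattens
        x1, x2 = 1.5, 3.0
        m = cc.RestrictedPowerLaw(gamma=2.0, x_min=1.0, x_max=1e7)
        assert m.pdf(x1) / m.pdf(x2) == pytest.approx(1.0, abs=1e-5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            cc.RestrictedPowerLaw(gamma=-1.0, x_min=0.0, x_max=1.0)
        with pytest.raises(ParameterError):
            cc.RestrictedPowerLaw(gamma=1.0, x_min=2.0, x_max=1.0)


class TestTruncatedPowerLaw:
    def test_exponential_limit_density(self):
        # alpha=1 reduces to an exponential: density at the lower bound is 1/x_c
        m = cc.TruncatedPowerLaw(alpha=1.0, x_c=2.0, x_min=1e-6)
        assert m.pdf(m.x_min) == pytest.approx(0.5, rel=1e-5)

    def test_normalization_reference_params(self):
        m = cc.TruncatedPowerLaw(**TRUNCATED_REF)
        assert quad(m.pdf, m.x_min, np.inf)[0] == pytest.approx(1.0, abs=1e-8)

    def test_mode_and_monotone_tail(self):
        m = cc.TruncatedPowerLaw(alpha=3.0, x_c=2.0, x_min=0.1)
        mode = (m.alpha - 1) * m.x_c
        xs = np.linspace(mode, mode + 30, 200)
        dens = m.pdf(xs)
        assert np.all(np.diff(dens) < 0)

    def test_negative_alpha_normalizes(self):
        m = cc.TruncatedPowerLaw(alpha=-0.5, x_c=3.0, x_min=0.5)
        assert quad(m.pdf, m.x_min, np.inf)[0] == pytest.approx(1.0, abs=1e-8)

    def test_mean_matches_quadrature(self):
        m = cc.TruncatedPowerLaw(**TRUNCATED_REF)
        num = quad(lambda x: x * m.pdf(x), m.x_min, np.inf)[0]
        assert m.mean() == pytest.approx(num, rel=1e-8)

    def test_large_cutoff_approaches_power_shape(self):
        # on a compact window the shape tends to x**(alpha-1) as x_c -> inf
        m = cc.TruncatedPowerLaw(alpha=-1.5, x_c=1e8, x_min=1.0)
        x1, x2 = 2.0, 8.0
        assert m.pdf(x1) / m.pdf(x2) == pytest.approx(
            (x1 / x2) ** (m.alpha - 1), rel=1e-5
        )

    def test_cdf_monotone_with_unit_range(self):
        m = cc.TruncatedPowerLaw(**TRUNCATED_REF)
        xs = np.linspace(m.x_min, m.x_min + 20 * m.x_c, 60)
        F = m.cdf(xs)
        assert np.all(np.diff(F) >= 0)
        assert F[0] == pytest.approx(0.0, abs=1e-12)
        assert F[-1] == pytest.approx(1.0, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            cc.TruncatedPowerLaw(alpha=1.0, x_c=-1.0, x_min=0.5)
        with pytest.raises(ParameterError):
            cc.TruncatedPowerLaw(alpha=1.0, x_c=1.0, x_min=0.0)


class TestPowerLaw:
    def test_boundary_and_pointwise_values(self):
        m = cc.PowerLaw(alpha=2.0, x_min=1.0)
        assert m.pdf(1.0) == pytest.approx(1.0)  # (alpha-1)/x_min
        assert m.pdf(2.0) == pytest.approx(0.25)
        assert quad(m.pdf, 1.0, np.inf)[0] == pytest.approx(1.0, abs=1e-8)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            cc.PowerLaw(alpha=1.0, x_min=1.0)


@pytest.mark.parametrize(
    "model_id,params",
    [
        ("restricted", RESTRICTED_REF),
        ("truncated", TRUNCATED_REF),
        ("powerlaw", POWERLAW_REF),
    ],
)
class TestSampling:
    def test_deterministic_under_seed(self, model_id, params):
        a = cc.sample(model_id, params, 100, seed=7)
        b = cc.sample(model_id, params, 100, seed=7)
        assert np.array_equal(a, b)

    def test_ks_distance_below_critical(self, model_id, params):
        # 1% critical value of the one-sample KS statistic is 1.63/sqrt(n)
        n = 10_000
        model = cc.make_model(model_id, params)
        draws = cc.sample(model_id, params, n, seed=11)
        stat = kstest(draws, model.cdf).statistic
        assert stat < 1.63 / math.sqrt(n)


class TestSamplerEdges:
    def test_uniform_limit_mean(self):
        m = dict(gamma=0.0, x_min=1.0, x_max=3.0)
        draws = cc.sample("restricted", m, 100_000, seed=3)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_truncated_root_finding_branch(self):
        # alpha <= 0 exercises the bracketed-root-finding inverse
        model = cc.TruncatedPowerLaw(alpha=-0.5, x_c=3.0, x_min=0.5)
        draws = model.sample(100, np.random.default_rng(0))
        assert np.all(draws >= model.x_min)
        stat = kstest(draws, model.cdf).statistic
        assert stat < 1.63 / math.sqrt(draws.size)

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            cc.sample("lognormal", {"mu": 0.0}, 10, seed=0)
        with pytest.raises(ConfigurationError):
            cc.make_model("restricted", {"nope": 1.0})

    def test_icdf_domain_checked(self):
        m = cc.RestrictedPowerLaw(**RESTRICTED_REF)
        with pytest.raises(ParameterError):
            m.icdf(1.5)


def test_densities_integrate_to_one_random_grid(rng):
    """All three families normalise across a randomised parameter grid."""
    for _ in range(20):
        g = rng.uniform(-0.8, 5.0)
        lo = rng.uniform(0.05, 2.0)
        m = cc.RestrictedPowerLaw(gamma=g, x_min=lo, x_max=lo + rng.uniform(0.5, 40))
        assert quad(m.pdf, m.x_min, m.x_max)[0] == pytest.approx(1.0, abs=1e-8)
        t = cc.TruncatedPowerLaw(
            alpha=rng.uniform(0.3, 4.0), x_c=rng.uniform(0.5, 20), x_min=lo
        )
        assert quad(t.pdf, t.x_min, np.inf)[0] == pytest.approx(1.0, abs=1e-8)
        p = cc.PowerLaw(alpha=rng.uniform(1.5, 4.0), x_min=lo)
        assert quad(p.pdf, p.x_min, np.inf)[0] == pytest.approx(1.0, abs=1e-8)
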