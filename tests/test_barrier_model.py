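"""Barrier-crossing process: closed forms, oracles, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recbarrier.barrier_model import (BarrierParams, DivergenceMap,
                                      autocatalytic_rates_from_shape,
                                      autocatalytic_shape_from_rates,
                                      crossing_density, delay,
                                      delay_quadrature, recombining_fraction,
                                      recombining_fraction_ode, tau_infinity,
                                      sample_crossing_times, xi_from_phi)


def params_for(scenario: str) -> BarrierParams:
    return {
        "power_law": BarrierParams.power_law(3.0, 1.5),
        "linear": BarrierParams.linear(40.0),
        "linear_plus_constant": BarrierParams.linear_plus_constant(2.0, 30.0),
        "autocatalytic": BarrierParams.autocatalytic(0.1, 5.0),
    }[scenario]


ALL_SCENARIOS = ["power_law", "linear", "linear_plus_constant", "autocatalytic"]


class TestRecombiningFraction:
    def test_initial_condition(self):
        for s in ALL_SCENARIOS:
            assert recombining_fraction(params_for(s), 0.0) == pytest.approx(1.0)

    def test_constant_hazard_is_exponential(self):
        p = BarrierParams.power_law(1.0, 0.0)
        assert recombining_fraction(p, 1.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_autocatalytic_f0_forced_by_normalizer(self):
        # the xi normalizer makes G'(0) = 0, i.e. f(0) = 1, for any phi
        for phi in (0.5, 2.0, 5.0, 20.0, 50.0):
            p = BarrierParams.autocatalytic(0.1, phi)
            assert recombining_fraction(p, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            recombining_fraction(params_for("linear"), -0.1)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            BarrierParams("sigmoid", lambda0=1.0)

    @pytest.mark.parametrize("scenario", ALL_SCENARIOS)
    def test_matches_ode_oracle(self, scenario):
        p = params_for(scenario)
        tmax = 10.0 * tau_infinity(p)
        grid = np.linspace(0.0, tmax, 40)
        closed = recombining_fraction(p, grid)
        numeric = recombining_fraction_ode(p, grid)
        assert np.max(np.abs(closed - numeric)) < 1e-6


class TestCrossingDensity:
    def test_equals_minus_df_dt(self):
        p = BarrierParams.power_law(1.0, 0.0)
        assert crossing_density(p, 0.0) == pytest.approx(1.0)
        # finite differences across scenarios
        for s in ALL_SCENARIOS:
            q = params_for(s)
            for t in (0.01, 0.05, 0.2):
                h = 1e-6
                fd = -(recombining_fraction(q, t + h) - recombining_fraction(q, t - h)) / (2 * h)
                assert crossing_density(q, t) == pytest.approx(fd, rel=1e-5, abs=1e-7)

    @pytest.mark.parametrize("scenario", ALL_SCENARIOS)
    def test_integral_is_one_minus_f(self, scenario):
        from scipy.integrate import quad

        p = params_for(scenario)
        T = 3.0 * tau_infinity(p)
        val, _ = quad(lambda u: crossing_density(p, u), 0.0, T, limit=200)
        assert val == pytest.approx(1.0 - recombining_fraction(p, T), abs=1e-8)

    def test_autocatalytic_density_unimodal(self):
        p = BarrierParams.autocatalytic(0.1, 5.0)
        grid = np.linspace(0, 0.5, 400)
        d = np.asarray(crossing_density(p, grid))
        peak = int(np.argmax(d))
        assert 0 < peak < len(grid) - 1
        assert np.all(np.diff(d[:peak + 1]) >= -1e-9)
        assert np.all(np.diff(d[peak:]) <= 1e-9)


class TestDelay:
    def test_zero_at_origin(self):
        for s in ALL_SCENARIOS:
            assert delay(params_for(s), 0.0) == 0.0

    def test_constant_hazard_saturates_at_inverse_rate(self):
        p = BarrierParams.power_law(1.0, 0.0)
        assert tau_infinity(p) == pytest.approx(1.0)
        assert delay(p, 50.0) == pytest.approx(1.0, abs=1e-12)

    def test_autocatalytic_saturation(self):
        p = BarrierParams.autocatalytic(0.1, 5.0)
        assert delay(p, 1.0) == pytest.approx(0.1, abs=1e-3)

    @pytest.mark.parametrize("scenario", ALL_SCENARIOS)
    def test_matches_quadrature_oracle(self, scenario):
        p = params_for(scenario)
        for t in (0.01, 0.1, 0.3, 1.0):
            assert delay(p, t) == pytest.approx(delay_quadrature(p, t), abs=1e-6)


class TestDivergenceMap:
    def test_autocatalytic_closed_form_endpoints(self, autocat):
        m = DivergenceMap(autocat)
        assert m.forward(0.0) == 0.0
        assert m.forward(5.0) == pytest.approx(5.0 - 0.1, abs=1e-6)

    def test_identity_limit(self):
        # a very fast constant hazard means essentially no delay
        m = DivergenceMap(BarrierParams.power_law(1e9, 0.0))
        assert m.forward(0.5) == pytest.approx(0.5, abs=1e-8)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_inverse_round_trip(self, autocat, t):
        m = DivergenceMap(autocat)
        assert m.inverse(m.forward(t)) == pytest.approx(t, rel=1e-10, abs=1e-12)

    def test_inverse_at_zero_and_bracket(self, autocat):
        m = DivergenceMap(autocat)
        assert m.inverse(0.0) == 0.0
        t = m.inverse(1.0)
        assert 1.0 < t <= 1.1 + 1e-9

    def test_negative_divergence_rejected(self, autocat):
        with pytest.raises(ValueError):
            DivergenceMap(autocat).inverse(-0.5)

    def test_pairwise_factor_two(self, autocat):
        m = DivergenceMap(autocat)
        assert m.pairwise(0.3) == pytest.approx(2.0 * m.forward(0.3))


@st.composite
def barrier_params(draw):
    scenario = draw(st.sampled_from(ALL_SCENARIOS))
    if scenario == "power_law":
        return BarrierParams.power_law(
            draw(st.floats(0.1, 50.0)), draw(st.floats(0.0, 3.0)))
    if scenario == "linear":
        return BarrierParams.linear(draw(st.floats(0.5, 200.0)))
    if scenario == "linear_plus_constant":
        return BarrierParams.linear_plus_constant(
            draw(st.floats(0.1, 20.0)), draw(st.floats(0.5, 200.0)))
    return BarrierParams.autocatalytic(
        draw(st.floats(0.01, 1.0)), draw(st.floats(0.5, 50.0)))


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(barrier_params())
    def test_shape_invariants(self, p):
        ti = tau_infinity(p)
        grid = np.linspace(0.0, 5.0 * ti, 30)
        f = np.asarray(recombining_fraction(p, grid))
        assert np.all((f >= -1e-12) & (f <= 1.0 + 1e-12))
        assert np.all(np.diff(f) <= 1e-12)
        tau = np.asarray(delay(p, grid))
        assert np.all(np.diff(tau) >= -1e-12)  # non-decreasing
        assert np.all(np.diff(tau, 2) <= 1e-9)  # concave
        assert np.all(tau <= np.minimum(grid, ti) + 1e-9)
        g = grid - tau
        assert np.all(np.diff(g) >= -1e-12)
        assert np.all((g >= -1e-9) & (g <= grid + 1e-12))

    @pytest.mark.parametrize("phi", [0.5, 1.0, 5.0, 20.0, 50.0])
    def test_normalizer_zeroes_initial_slope(self, phi):
        m = DivergenceMap(BarrierParams.autocatalytic(0.2, phi))
        h = 1e-7
        slope0 = m.forward(h) / h
        assert abs(slope0) < 1e-4

    def test_rate_shape_conversion_round_trip(self):
        l0, l1 = autocatalytic_rates_from_shape(0.1, 5.0)
        assert l0 > l1 > 0
        ti, phi = autocatalytic_shape_from_rates(l0, l1)
        assert ti == pytest.approx(0.1, rel=1e-12)
        assert phi == pytest.approx(5.0, rel=1e-12)

    def test_xi_requires_positive_phi(self):
        with pytest.raises(ValueError):
            xi_from_phi(0.0)


class TestSampling:
    def test_crossing_time_sample_matches_density_mean(self):
        p = BarrierParams.autocatalytic(0.1, 5.0)
        rng = np.random.default_rng(5)
        s = sample_crossing_times(p, 20000, rng)
        # E[u] = tau_inf when f decays to 0
        assert s.mean() == pytest.approx(0.1, rel=0.05)

    def test_censoring(self):
        p = BarrierParams.linear(5.0)
        rng = np.random.default_rng(6)
        s = sample_crossing_times(p, 500, rng, t_max=0.05)
        assert s.max() <= 0.05


class TestSerialization:
    def test_json_round_trip(self, autocat):
        q = BarrierParams.from_json(autocat.to_json())
        assert q.scenario == "autocatalytic"
        assert q.tau_inf == pytest.approx(autocat.tau_inf)
        assert q.phi == pytest.approx(autocat.phi)
        assert "xi" not in autocat.to_dict()

    def test_autocatalytic_requires_consistent_parameters(self):
        with pytest.raises(ValueError):
            BarrierParams("autocatalytic", tau_inf=0.1)  # phi missing
        with pytest.raises(ValueError):
            BarrierParams("autocatalytic", lambda0=1.0, lambda1=2.0)  # hazard < 0
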