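"""Kernel closed-form oracles, linearity and conservation properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herdclim import (
    EmissionsPathway,
    EmulatorParams,
    ch4_concentration,
    co2_concentration,
    forcing_from_concentration,
    metric,
    temperature_from_forcing,
    warming_from_emissions,
)
from herdclim.emulator import ForcingSeries, co2_irf
from herdclim.params import GasCycleParams, ThermalParams

AR5_THERMAL = ThermalParams(q=(0.631, 0.429), d=(8.4, 409.5))


def pulse(gas, mass, n):
    v = np.zeros(n)
    v[0] = mass
    return EmissionsPathway(gas, np.arange(n), v)


def constant(gas, level, n):
    return EmissionsPathway(gas, np.arange(n), np.full(n, float(level)))


class TestCo2Concentration:
    def test_zero_emissions_zero_anomaly(self, params):
        c = co2_concentration(constant("co2_net", 0.0, 50), params)
        assert np.all(c.values == 0.0)

    def test_pulse_asymptote_is_persistent_fraction(self, params):
        # 1000 Gt pulse: only a0 = 0.2173 of 1000/7.814 ppm remains at t -> inf
        c = co2_concentration(pulse("co2_net", 1000.0, 5001), params)
        expected = 1000.0 / 7.814 * 0.2173
        assert c.values[-1] == pytest.approx(expected, rel=1e-4)

    def test_linearity_in_emissions(self, params, rng):
        n = 80
        a = EmissionsPathway("co2_net", np.arange(n), rng.normal(size=n))
        b = EmissionsPathway("co2_net", np.arange(n), rng.normal(size=n))
        ab = EmissionsPathway("co2_net", np.arange(n), a.values + b.values)
        np.testing.assert_allclose(
            co2_concentration(ab, params).values,
            co2_concentration(a, params).values + co2_concentration(b, params).values,
            atol=1e-12,
        )

    def test_wrong_gas_rejected(self, params):
        with pytest.raises(ValueError, match="co2_net"):
            co2_concentration(constant("ch4_livestock", 1.0, 5), params)

    def test_irf_fractions_conserved(self):
        gas = GasCycleParams()
        assert gas.co2_a0 + sum(gas.co2_a) == pytest.approx(1.0, abs=1e-9)
        # instantaneous airborne fraction of a fresh pulse is exactly 1
        assert co2_irf(0.0, gas) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_fraction_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GasCycleParams(co2_a0=0.5)


class TestCh4Concentration:
    def test_steady_state_is_e_tau_over_m(self, params):
        # constant 27.5 Mt/yr, tau 12 yr, 2.75 Mt/ppb -> 120 ppb
        c = ch4_concentration(constant("ch4_livestock", 27.5, 250), params)
        assert c.values[-1] == pytest.approx(120.0, rel=1e-6)

    def test_pulse_decays_with_lifetime(self, params):
        # 275 Mt pulse: ~100 ppb decaying as exp(-t/12); year-end reporting of
        # a mid-year pulse means index k sits at physical time k + 0.5
        c = ch4_concentration(pulse("ch4_livestock", 275.0, 120), params)
        t = np.arange(20, 100)
        oracle = 100.0 * np.exp(-(t + 0.5) / 12.0)
        np.testing.assert_allclose(c.values[t], oracle, rtol=2e-3)

    def test_nonnegative_emissions_give_nonnegative_anomaly(self, params, rng):
        v = rng.uniform(0, 50, size=100)
        c = ch4_concentration(EmissionsPathway("ch4_livestock", np.arange(100), v), params)
        assert np.all(c.values >= 0)


class TestForcing:
    def test_zero_anomaly_zero_forcing(self, params):
        c = ch4_concentration(constant("ch4_livestock", 0.0, 10), params)
        f = forcing_from_concentration(c, "ch4_livestock", params)
        assert np.all(f.values == 0.0)

    def test_ch4_direct_times_indirect(self, params):
        from herdclim.emulator import ConcentrationSeries

        c = ConcentrationSeries(np.arange(3), np.array([0.0, 100.0, 0.0]), unit="ppb")
        f = forcing_from_concentration(c, "ch4_livestock", params)
        assert f.values[1] == pytest.approx(3.63e-4 * 1.65 * 100.0)  # 0.0599 W/m2

    def test_co2_linearized_efficiency(self, params):
        from herdclim.emulator import ConcentrationSeries

        c = ConcentrationSeries(np.arange(2), np.array([0.0, 10.0]), unit="ppm")
        f = forcing_from_concentration(c, "co2_net", params)
        assert f.values[1] == pytest.approx(0.134)

    def test_log_mode_agrees_with_linear_for_small_anomaly(self):
        from herdclim.emulator import ConcentrationSeries

        c = ConcentrationSeries(np.arange(2), np.array([0.0, 1.0]), unit="ppm")
        lin = forcing_from_concentration(c, "co2_net", EmulatorParams())
        log = forcing_from_concentration(c, "co2_net", EmulatorParams().with_co2_mode("log"))
        assert log.values[1] == pytest.approx(lin.values[1], rel=0.01)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            GasCycleParams(co2_reference_ppm=-1.0)


class TestTemperature:
    def test_step_forcing_transient_matches_closed_form(self):
        # independent closed form: T(t) = sum_j q_j (1 - exp(-t/d_j))
        f = ForcingSeries(np.arange(50), np.ones(50), unit="W/m2")
        t = temperature_from_forcing(f, AR5_THERMAL)
        oracle = 0.631 * (1 - np.exp(-10 / 8.4)) + 0.429 * (1 - np.exp(-10 / 409.5))
        assert oracle == pytest.approx(0.449, abs=5e-4)
        # year-end value after 10 years of unit forcing (years 0..9)
        assert t.values[9] == pytest.approx(oracle, abs=1e-12)

    def test_step_forcing_asymptote_is_sum_q(self):
        f = ForcingSeries(np.arange(6000), np.ones(6000), unit="W/m2")
        t = temperature_from_forcing(f, AR5_THERMAL)
        assert t.values[-1] == pytest.approx(1.06, abs=1e-3)

    def test_step_response_monotone_nondecreasing(self, params):
        f = ForcingSeries(np.arange(300), np.ones(300), unit="W/m2")
        t = temperature_from_forcing(f, params.thermal)
        assert np.all(np.diff(t.values) >= -1e-15)

    def test_zero_forcing_zero_temperature(self, params):
        f = ForcingSeries(np.arange(5), np.zeros(5), unit="W/m2")
        assert np.all(temperature_from_forcing(f, params.thermal).values == 0.0)


class TestWarmingFromEmissions:
    def test_additivity_in_linearized_mode(self, params, rng):
        n = 60
        years = np.arange(2000, 2000 + n)
        a = EmissionsPathway("co2_net", years, rng.normal(size=n))
        b = EmissionsPathway("co2_net", years, rng.normal(size=n))
        ab = EmissionsPathway("co2_net", years, a.values + b.values)
        np.testing.assert_allclose(
            warming_from_emissions(ab, params).values,
            warming_from_emissions(a, params).values + warming_from_emissions(b, params).values,
            atol=1e-12,
        )

    def test_time_shift_equivariance(self, params):
        n, shift = 120, 15
        v = np.zeros(n)
        v[0] = 100.0
        base = warming_from_emissions(
            EmissionsPathway("ch4_livestock", np.arange(n), v), params
        ).values
        shifted = warming_from_emissions(
            EmissionsPathway("ch4_livestock", np.arange(n), np.roll(v, shift)), params
        ).values
        np.testing.assert_allclose(shifted[shift:], base[: n - shift], atol=1e-12)

    def test_ch4_pulse_agtp_matches_analytic_double_exponential(self, params):
        # independent continuous-time oracle for a 1 Mt pulse emitted mid-year:
        # T(t) = (1/m) * eff * mult * sum_j q_j/d_j * (e^(-t/tau)-e^(-t/d_j))/(1/d_j-1/tau)
        gas, th = params.gas, params.thermal
        horizon = 100
        t = horizon - 0.5
        amp = gas.ch4_wm2_per_ppb * gas.ch4_indirect / gas.mt_ch4_per_ppb
        oracle = amp * sum(
            (q / d) * (np.exp(-t / gas.ch4_lifetime) - np.exp(-t / d)) / (1 / d - 1 / gas.ch4_lifetime)
            for q, d in zip(th.q, th.d)
        )
        assert metric("ch4_livestock", horizon, params, kind="agtp") == pytest.approx(
            oracle, rel=0.01
        )


class TestMetrics:
    def test_gwp_of_co2_is_one(self, params):
        assert metric("co2_net", 100, params, kind="gwp") == pytest.approx(1.0)
        assert metric("co2_net", 20, params, kind="gwp") == pytest.approx(1.0)

    def test_gwp100_ch4_in_assessed_range_and_matches_integral_oracle(self, params):
        gwp = metric("ch4_livestock", 100, params, kind="gwp")
        assert 25.0 <= gwp <= 32.0
        # closed-form AGWP oracle (continuous-time integrals of both kernels)
        g = params.gas
        h = 100.0
        agwp_ch4 = (
            g.ch4_wm2_per_ppb * g.ch4_indirect / g.mt_ch4_per_ppb
        ) * g.ch4_lifetime * (1 - np.exp(-h / g.ch4_lifetime))
        irf_integral = g.co2_a0 * h + sum(
            a * tau * (1 - np.exp(-h / tau)) for a, tau in zip(g.co2_a, g.co2_tau)
        )
        agwp_co2_per_mt = g.co2_linear_wm2_per_ppm * irf_integral / g.gt_co2_per_ppm * 1e-3
        assert gwp == pytest.approx(agwp_ch4 / agwp_co2_per_mt, rel=0.03)

    def test_zero_mass_pulse_agtp_is_zero(self, params):
        assert metric("ch4_livestock", 50, params, kind="agtp", mass=0.0) == 0.0

    def test_invalid_horizon_and_gas(self, params):
        with pytest.raises(ValueError, match="horizon"):
            metric("ch4_livestock", 0, params)
        with pytest.raises(ValueError, match="unknown gas"):
            metric("n2o", 100, params, kind="agwp")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    level=st.floats(min_value=0.1, max_value=500.0),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_ch4_chain_is_homogeneous(level, scale):
    """Scaling emissions scales warming by the same factor (kernel linearity)."""
    params = EmulatorParams()
    p1 = constant("ch4_livestock", level, 60)
    p2 = constant("ch4_livestock", level * scale, 60)
    w1 = warming_from_emissions(p1, params).values
    w2 = warming_from_emissions(p2, params).values
    np.testing.assert_allclose(w2, scale * w1, rtol=1e-9)
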