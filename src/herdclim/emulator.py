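"""Pulse-response climate emulator: emissions -> concentration -> forcing -> warming.

The chain is the standard reduced-complexity emulator structure:

* CO2 airborne fraction follows an impulse response function
  ``IRF(t) = a0 + sum_i a_i exp(-t/tau_i)`` (a MAGICC-median-style
  calibration by default);
* CH4 follows a single well-mixed box, ``dC/dt = E/m - C/tau``;
* radiative forcing is linear in the CH4 anomaly (direct efficiency times an
  indirect-effects multiplier) and either linearized or logarithmic in CO2;
* temperature responds through a two-mode energy balance
  ``R(t) = sum_j (q_j/d_j) exp(-t/d_j)``.

Discretization: emissions and forcing are piecewise-constant over calendar
years and the exponential kernels are integrated analytically, so the annual
solver is exact for piecewise-constant input (refining the internal step
changes nothing). Anomalies are reported at year-end and are relative to the
start of the driving pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .params import EmulatorParams, GasCycleParams, ThermalParams
from .scenarios import EmissionsPathway

__all__ = [
    "ForcingSeries",
    "TemperatureSeries",
    "co2_irf",
    "co2_concentration",
    "ch4_concentration",
    "ConcentrationSeries",
    "forcing_from_concentration",
    "temperature_from_forcing",
    "warming_from_emissions",
    "metric",
]


@dataclass(frozen=True)
class _AnnualSeries:
    years: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.years.shape != self.values.shape:
            raise ValueError("years/values must match")

    def value_at(self, year: int) -> float:
        i = int(year) - int(self.years[0])
        if not 0 <= i < self.years.size:
            raise KeyError(f"year {year} outside series axis")
        return float(self.values[i])


@dataclass(frozen=True)
class ConcentrationSeries(_AnnualSeries):
    """Concentration anomaly (ppm for CO2, ppb for CH4) at year-end."""


@dataclass(frozen=True)
class ForcingSeries(_AnnualSeries):
    """Radiative forcing anomaly in W/m2 at year-end."""


@dataclass(frozen=True)
class TemperatureSeries(_AnnualSeries):
    """Warming anomaly in degC relative to the pathway start, at year-end."""


def _exp_kernel(n: int, tau: float) -> np.ndarray:
    """Year-end response to a unit rate held constant over one year.

    Exact integral of ``exp(-t/tau)`` against piecewise-constant input:
    lag-k response is ``tau (1 - e^(-1/tau)) e^(-k/tau)``.
    """
    k = np.arange(n)
    return tau * (1.0 - np.exp(-1.0 / tau)) * np.exp(-k / tau)


def _convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(x, kernel)[: x.size]


def co2_irf(t: np.ndarray | float, gas: GasCycleParams | None = None) -> np.ndarray | float:
    """Airborne fraction of a CO2 pulse after ``t`` years; IRF(0) = 1."""
    gas = gas or GasCycleParams()
    t = np.asarray(t, dtype=float)
    out = gas.co2_a0 + sum(a * np.exp(-t / tau) for a, tau in zip(gas.co2_a, gas.co2_tau))
    return float(out) if out.ndim == 0 else out


def co2_concentration(pathway: EmissionsPathway, params: EmulatorParams) -> ConcentrationSeries:
    """CO2 concentration anomaly (ppm): IRF convolution of annual emissions."""
    if pathway.gas != "co2_net":
        raise ValueError(f"expected a co2_net pathway, got {pathway.gas!r}")
    gas = params.gas
    e = pathway.values / gas.gt_co2_per_ppm
    c = gas.co2_a0 * np.cumsum(e)
    for a, tau in zip(gas.co2_a, gas.co2_tau):
        c = c + a * _convolve(e, _exp_kernel(e.size, tau))
    return ConcentrationSeries(pathway.years, c, unit="ppm")


def ch4_concentration(pathway: EmissionsPathway, params: EmulatorParams) -> ConcentrationSeries:
    """CH4 concentration anomaly (ppb) from the single-box decay model."""
    if pathway.gas != "ch4_livestock":
        raise ValueError(f"expected a CH4 pathway, got {pathway.gas!r}")
    gas = params.gas
    e = pathway.values / gas.mt_ch4_per_ppb
    c = _convolve(e, _exp_kernel(e.size, gas.ch4_lifetime))
    return ConcentrationSeries(pathway.years, c, unit="ppb")


def forcing_from_concentration(
    anomaly: ConcentrationSeries, gas: str, params: EmulatorParams
) -> ForcingSeries:
    """Radiative forcing from a concentration anomaly series."""
    g = params.gas
    if gas == "ch4_livestock":
        f = g.ch4_wm2_per_ppb * g.ch4_indirect * anomaly.values
    elif gas == "co2_net":
        if g.co2_forcing_mode == "linear":
            f = g.co2_linear_wm2_per_ppm * anomaly.values
        else:
            f = g.co2_log_coefficient * np.log1p(anomaly.values / g.co2_reference_ppm)
    else:
        raise ValueError(f"unknown gas {gas!r}")
    return ForcingSeries(anomaly.years, f, unit="W/m2")


def temperature_from_forcing(forcing: ForcingSeries, thermal: ThermalParams) -> TemperatureSeries:
    """Two-mode energy-balance convolution; a step forcing F asymptotes to F*sum(q)."""
    t = np.zeros(forcing.values.size)
    for q, d in zip(thermal.q, thermal.d):
        # kernel for T: integral of (q/d) e^{-t/d} against piecewise-constant F
        kernel = (q / d) * _exp_kernel(forcing.values.size, d)
        t = t + _convolve(forcing.values, kernel)
    return TemperatureSeries(forcing.years, t, unit="degC")


def warming_from_emissions(
    pathway: EmissionsPathway, params: EmulatorParams | None = None
) -> TemperatureSeries:
    """Full chain: emissions -> concentration -> forcing -> temperature."""
    params = params or EmulatorParams()
    if pathway.gas == "co2_net":
        conc = co2_concentration(pathway, params)
    else:
        conc = ch4_concentration(pathway, params)
    forcing = forcing_from_concentration(conc, pathway.gas, params)
    return temperature_from_forcing(forcing, params.thermal)


def _pulse(gas: str, mass: float, n: int) -> EmissionsPathway:
    values = np.zeros(n)
    values[0] = mass
    return EmissionsPathway(gas, np.arange(n), values, label="pulse")


def metric(
    gas: str,
    horizon: int,
    params: EmulatorParams | None = None,
    kind: Literal["agwp", "agtp", "gwp"] = "gwp",
    mass: float = 1.0,
) -> float:
    """Pulse emission metrics at a time horizon (years).

    AGWP: time-integrated forcing of a pulse, W/m2 yr per Mt emitted.
    AGTP: pulse temperature at the horizon, degC per Mt emitted.
    GWP: AGWP ratio to CO2 on an equal-mass basis (GWP of CO2 is 1).
    ``mass`` scales the emitted pulse (Mt); metrics are reported per Mt so the
    value is mass-independent in linearized mode.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    params = params or EmulatorParams()
    if kind == "gwp":
        num = metric(gas, horizon, params, kind="agwp", mass=mass)
        den = metric("co2_net", horizon, params, kind="agwp", mass=mass)
        return num / den
    if gas not in ("co2_net", "ch4_livestock"):
        raise ValueError(f"unknown gas {gas!r}")
    if mass == 0.0:
        return 0.0
    n = horizon + 1
    if gas == "co2_net":
        # emulator works in Gt for CO2; convert a pulse of `mass` Mt
        pathway = _pulse("co2_net", mass * 1e-3, n)
    else:
        pathway = _pulse("ch4_livestock", mass, n)
    if gas == "co2_net":
        conc = co2_concentration(pathway, params)
    else:
        conc = ch4_concentration(pathway, params)
    forcing = forcing_from_concentration(conc, gas, params)
    if kind == "agwp":
        # forcing values are year-end points of a piecewise-exponential decay;
        # annual sum approximates the integral over [0, horizon]
        return float(np.sum(forcing.values[:horizon])) / mass
    if kind == "agtp":
        temp = temperature_from_forcing(forcing, params.thermal)
        return float(temp.values[horizon]) / mass
    raise ValueError(f"unknown metric kind {kind!r}")
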