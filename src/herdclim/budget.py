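"""Carbon-budget diagnostics, temperature-matched pathway inversion and the
CH4 stabilization-rate finder.

The inversion answers: if livestock CH4 follows a warmer alternative pathway
(e.g. business-as-usual growth instead of deep cuts), how much lower and
earlier must net CO2 go for the combined modelled warming to stay the same?
The answer is summarized as a change in the remaining carbon budget
(cumulative net CO2 from a start year to the net-zero year), in the net-zero
year itself, and in the 2020-2030 reduction rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .emulator import TemperatureSeries, warming_from_emissions
from .params import EmulatorParams
from .scenarios import EmissionsPathway

__all__ = [
    "BudgetReport",
    "InversionSpec",
    "InversionError",
    "net_zero_year",
    "annual_reduction_rate",
    "cumulative_to_net_zero",
    "budget_report",
    "adjust_co2_for_ch4",
    "budget_fraction",
    "stabilizing_decline_rate",
]


def net_zero_year(pathway: EmissionsPathway) -> float | None:
    """First downward zero-crossing, linearly interpolated; None if never."""
    v = pathway.values
    y = pathway.years
    if v[0] <= 0.0:
        return float(y[0])
    for i in range(1, v.size):
        if v[i] <= 0.0 < v[i - 1]:
            frac = v[i - 1] / (v[i - 1] - v[i]) if v[i] < 0.0 else 1.0
            return float(y[i - 1]) + float(frac)
    return None


def annual_reduction_rate(pathway: EmissionsPathway, y0: int, y1: int) -> float:
    """Geometric mean decline rate between two years, in %/yr."""
    v0, v1 = pathway.value_at(y0), pathway.value_at(y1)
    if v0 <= 0 or v1 <= 0:
        raise ValueError("endpoint values must be strictly positive")
    return 100.0 * (1.0 - (v1 / v0) ** (1.0 / (y1 - y0)))


def cumulative_to_net_zero(pathway: EmissionsPathway, start_year: int) -> float:
    """Trapezoidal integral of net emissions from ``start_year`` to net-zero (Gt).

    Propagates a "never reaches net-zero" pathway as None.
    """
    nz = net_zero_year(pathway)
    if nz is None:
        return None
    i0 = int(start_year) - int(pathway.years[0])
    if not 0 <= i0 < pathway.years.size:
        raise ValueError(f"start year {start_year} outside pathway axis")
    k = int(np.floor(nz)) - int(pathway.years[0])
    total = float(np.trapezoid(pathway.values[i0 : k + 1], pathway.years[i0 : k + 1]))
    frac = nz - np.floor(nz)
    if frac > 0:
        # triangle from the last positive year down to the crossing
        total += 0.5 * pathway.values[k] * frac
    return total


@dataclass(frozen=True)
class BudgetReport:
    """Net-zero/rate/cumulative diagnostics for one CO2 pathway."""

    label: str
    net_zero: float | None
    reduction_rate_pct: float
    rate_window: tuple[int, int]
    cumulative_gt: float | None
    budget_start_year: int
    deltas: dict[str, float] = field(default_factory=dict)


def budget_report(
    pathway: EmissionsPathway,
    budget_start_year: int = 2018,
    rate_window: tuple[int, int] = (2020, 2030),
    reference: "BudgetReport | None" = None,
) -> BudgetReport:
    nz = net_zero_year(pathway)
    cum = cumulative_to_net_zero(pathway, budget_start_year)
    rate = annual_reduction_rate(pathway, *rate_window)
    deltas = {}
    if reference is not None:
        if nz is not None and reference.net_zero is not None:
            deltas["net_zero"] = nz - reference.net_zero
        deltas["reduction_rate_pct"] = rate - reference.reduction_rate_pct
        if cum is not None and reference.cumulative_gt is not None:
            deltas["cumulative_gt"] = cum - reference.cumulative_gt
    return BudgetReport(
        label=pathway.label,
        net_zero=nz,
        reduction_rate_pct=rate,
        rate_window=rate_window,
        cumulative_gt=cum,
        budget_start_year=budget_start_year,
        deltas=deltas,
    )


@dataclass(frozen=True)
class InversionSpec:
    """Inputs for the temperature-matched CO2 inversion.

    The adjusted-CO2 family has two parameters: the reference decline
    increments over ``adjust_window`` are scaled by s (steeper near-term
    cuts, earlier net-zero), and the resulting offset from the reference
    trajectory decays back to the pinned end-of-century floor with shape
    ``((end - t)/(end - t1))^u`` (small u keeps removals deeper for longer).
    (s, u) are root-found so the combined-warming difference vanishes at
    ``match_years``; success additionally requires the max absolute
    difference over ``match_window`` to be within ``tolerance``.
    """

    co2_ref: EmissionsPathway
    ch4_ref: EmissionsPathway
    ch4_alt: EmissionsPathway
    split_year: int = 2020
    adjust_window: tuple[int, int] = (2020, 2035)
    match_window: tuple[int, int] = (2020, 2100)
    match_years: tuple[int, int] = (2050, 2100)
    tolerance: float = 0.01  # degC
    scale_bracket: tuple[float, float] = (0.5, 3.0)
    shape_bracket: tuple[float, float] = (0.05, 3.0)
    budget_start_year: int = 2018
    rate_window: tuple[int, int] = (2020, 2030)

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        mask = self.ch4_alt.years >= self.split_year
        if np.any(self.ch4_alt.values[mask] < self.ch4_ref.values[mask] - 1e-9):
            raise ValueError("alternative CH4 must be >= reference CH4 after the split")


class InversionError(RuntimeError):
    """Raised when the one-parameter family cannot match temperatures."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (achieved residual {residual:.4f} degC)")
        self.residual = residual


def _adjusted_co2(spec: InversionSpec, s: float, u: float) -> EmissionsPathway:
    """Member (s, u) of the adjusted-CO2 pathway family."""
    ref = spec.co2_ref
    y0, y1 = spec.adjust_window
    years = ref.years
    v = ref.values.copy()
    i0 = int(y0) - int(years[0])
    i1 = int(y1) - int(years[0])
    inc = np.diff(ref.values[i0 : i1 + 1])
    v[i0 + 1 : i1 + 1] = v[i0] + np.cumsum(s * inc)
    offset = v[i1] - ref.values[i1]
    t = years[i1 + 1 :].astype(float)
    weight = ((years[-1] - t) / float(years[-1] - y1)) ** u
    v[i1 + 1 :] = ref.values[i1 + 1 :] + offset * weight
    return EmissionsPathway("co2_net", years, v, label=f"{ref.label}|adjusted")


def _warming_mismatch(
    spec: InversionSpec, params: EmulatorParams, s: float, u: float
) -> np.ndarray:
    """Combined-warming difference (adjusted+alt) - (reference) on the full axis."""
    co2_adj = _adjusted_co2(spec, s, u)
    return (
        warming_from_emissions(co2_adj, params).values
        - warming_from_emissions(spec.co2_ref, params).values
        + warming_from_emissions(spec.ch4_alt, params).values
        - warming_from_emissions(spec.ch4_ref, params).values
    )


def adjust_co2_for_ch4(
    spec: InversionSpec, params: EmulatorParams | None = None
) -> tuple[EmissionsPathway, BudgetReport]:
    """Temperature-matched CO2 inversion.

    Nested bracketed root-finds: for each rejoin shape u, the decline scale s
    is solved so the warming difference vanishes at the first match year;
    u is then solved so it vanishes at the second. Success requires the max
    absolute difference over the match window to stay within the tolerance.
    Returns the adjusted pathway and a BudgetReport with deltas versus the
    reference CO2 pathway.
    """
    params = params or EmulatorParams()
    years = spec.co2_ref.years
    i_mid = int(spec.match_years[0]) - int(years[0])
    i_end = int(spec.match_years[1]) - int(years[0])
    window = (years >= spec.match_window[0]) & (years <= spec.match_window[1])
    s_lo, s_hi = spec.scale_bracket
    u_lo, u_hi = spec.shape_bracket

    def solve_scale(u: float) -> float:
        f = lambda s: _warming_mismatch(spec, params, s, u)[i_mid]
        f_lo, f_hi = f(s_lo), f(s_hi)
        if f_lo * f_hi > 0:
            s_best = s_lo if abs(f_lo) < abs(f_hi) else s_hi
            resid = float(np.abs(_warming_mismatch(spec, params, s_best, u)[window]).max())
            raise InversionError("no sign change in the scale bracket", resid)
        return brentq(f, s_lo, s_hi, xtol=1e-4)

    if float(np.abs(spec.ch4_alt.values - spec.ch4_ref.values).max()) < 1e-12:
        s_opt, u_opt = 1.0, 1.0  # identical CH4: the reference CO2 already matches
    else:
        def end_mismatch(u: float) -> float:
            return _warming_mismatch(spec, params, solve_scale(u), u)[i_end]

        g_lo, g_hi = end_mismatch(u_lo), end_mismatch(u_hi)
        if g_lo * g_hi > 0:
            u_best = u_lo if abs(g_lo) < abs(g_hi) else u_hi
            s_best = solve_scale(u_best)
            resid = float(np.abs(_warming_mismatch(spec, params, s_best, u_best)[window]).max())
            raise InversionError("no sign change in the rejoin-shape bracket", resid)
        u_opt = brentq(end_mismatch, u_lo, u_hi, xtol=1e-4)
        s_opt = solve_scale(u_opt)
    residual = float(np.abs(_warming_mismatch(spec, params, s_opt, u_opt)[window]).max())
    if residual > spec.tolerance:
        raise InversionError("family cannot match temperatures to tolerance", residual)
    adjusted = _adjusted_co2(spec, s_opt, u_opt)
    ref_report = budget_report(spec.co2_ref, spec.budget_start_year, spec.rate_window)
    report = budget_report(adjusted, spec.budget_start_year, spec.rate_window, reference=ref_report)
    return adjusted, report


def budget_fraction(delta_gt: float, reference_budget_gt: float) -> float:
    """Budget change as a percentage of a reference budget."""
    if reference_budget_gt <= 0:
        raise ValueError("reference budget must be positive")
    return 100.0 * delta_gt / reference_budget_gt


def stabilizing_decline_rate(
    baseline_ch4_level: float,
    params: EmulatorParams | None = None,
    window: int = 50,
    spin_up: int = 60,
    bracket: tuple[float, float] = (0.0, 1.0),
    xtol: float = 1e-4,
) -> float:
    """Constant exponential CH4 decline rate (%/yr) that stabilizes warming.

    Emissions are held at ``baseline_ch4_level`` for ``spin_up`` years —
    five CH4 lifetimes by default, so the concentration is within 1 % of
    steady state while the slow thermal mode is still far from equilibrium,
    mimicking the present-day CH4 state — then decline at rate r; bisection
    finds the r for which warming at the window end equals warming at its
    start.
    """
    if baseline_ch4_level <= 0:
        raise ValueError("baseline level must be positive")
    if window < 40:
        raise ValueError("window must be at least 40 years")
    params = params or EmulatorParams()
    n = spin_up + window + 1
    years = np.arange(n)

    def end_minus_start(rate_pct: float) -> float:
        v = np.full(n, float(baseline_ch4_level))
        decl = years >= spin_up
        v[decl] = baseline_ch4_level * (1.0 - rate_pct / 100.0) ** (years[decl] - spin_up)
        t = warming_from_emissions(
            EmissionsPathway("ch4_livestock", years, v), params
        ).values
        return float(t[-1] - t[spin_up])

    lo, hi = bracket
    f_lo, f_hi = end_minus_start(lo), end_minus_start(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change in bracket {bracket}: f({lo})={f_lo:.2e}, f({hi})={f_hi:.2e}"
        )
    return float(brentq(end_minus_start, lo, hi, xtol=xtol))
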