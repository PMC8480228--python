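"""Emission-pathway data model, IAMC-style CSV I/O and scenario generators.

The generators produce stylized annual global pathways for net CO2 (Gt CO2/yr)
and livestock CH4 (Mt CH4/yr) that reproduce the headline shape facts of deep
(1.5 degC-consistent) mitigation scenarios and of a business-as-usual livestock
projection:

* net CO2 starts near 35 Gt/yr in 2020, declines geometrically at 4.9 %/yr to
  2030, reaches net-zero in 2055 and turns net-negative towards 2100, with the
  cumulative total from 2018 to net-zero calibrated to 580 Gt CO2;
* livestock CH4 drops 38 % by 2050 relative to 2010 (70 Mt/yr in 2050) and
  declines further to 2100 under mitigation, or grows 30 % by 2050 and is held
  constant thereafter under business-as-usual.

All generators are deterministic functions of their configuration.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "GAS_UNITS",
    "EmissionsPathway",
    "ScenarioAnchors",
    "ScenarioConfig",
    "build_pathway_from_anchors",
    "make_mitigation_scenario",
    "make_bau_livestock_ch4",
    "historical_backdrop",
    "read_iamc_csv",
    "write_iamc_csv",
    "data_path",
]

#: gas identifier -> (IAMC variable name, unit string)
GAS_UNITS = {
    "co2_net": ("Emissions|CO2", "Gt CO2/yr"),
    "ch4_livestock": ("Emissions|CH4|Livestock", "Mt CH4/yr"),
}


@dataclass(frozen=True)
class EmissionsPathway:
    """Annual global emissions for one gas on a contiguous year axis.

    ``co2_net`` may be negative (net removals); ``ch4_livestock`` must be
    non-negative. Values are totals for the calendar year.
    """

    gas: str
    years: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if self.gas not in GAS_UNITS:
            raise ValueError(f"unknown gas {self.gas!r}")
        if years.ndim != 1 or years.size == 0 or values.shape != years.shape:
            raise ValueError("years/values must be matching 1-d arrays")
        if years.size > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must be contiguous with step 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.gas == "ch4_livestock" and np.any(values < 0):
            raise ValueError("ch4_livestock emissions must be >= 0")

    @property
    def unit(self) -> str:
        return GAS_UNITS[self.gas][1]

    def value_at(self, year: int) -> float:
        i = int(year) - int(self.years[0])
        if not 0 <= i < self.years.size:
            raise KeyError(f"year {year} outside pathway axis")
        return float(self.values[i])

    def zeroed_after(self, split_year: int) -> "EmissionsPathway":
        """Copy with all emissions after ``split_year`` set to zero."""
        values = np.where(self.years > split_year, 0.0, self.values)
        return replace(self, values=values, label=f"{self.label}|<= {split_year}")

    def extended_to(self, end_year: int, fill: float = 0.0) -> "EmissionsPathway":
        """Copy padded with ``fill`` out to ``end_year``."""
        if end_year <= self.years[-1]:
            return self
        extra = np.arange(self.years[-1] + 1, end_year + 1)
        return replace(
            self,
            years=np.concatenate([self.years, extra]),
            values=np.concatenate([self.values, np.full(extra.size, fill)]),
        )


@dataclass(frozen=True)
class ScenarioAnchors:
    """(year, value) control points plus interpolation/extrapolation rules.

    ``kind`` is ``"pchip"`` (monotone shape-preserving piecewise cubic; never
    overshoots the local anchor range) or ``"linear"``. Outside the anchor span
    the nearest anchor value is held constant.
    """

    anchors: Sequence[tuple[int, float]]
    kind: str = "pchip"

    def __post_init__(self):
        if len(self.anchors) < 1:
            raise ValueError("need at least one anchor")
        ys = [y for y, _ in self.anchors]
        if any(b <= a for a, b in zip(ys, ys[1:])):
            raise ValueError("anchor years must be strictly increasing")
        if not all(1850 <= y <= 2100 for y in ys):
            raise ValueError("anchor years must lie within [1850, 2100]")
        if self.kind not in ("pchip", "linear"):
            raise ValueError(f"unknown interpolation rule {self.kind!r}")


def _interp_anchors(anchors: ScenarioAnchors, years: np.ndarray) -> np.ndarray:
    ay = np.array([y for y, _ in anchors.anchors], dtype=float)
    av = np.array([v for _, v in anchors.anchors], dtype=float)
    if ay.size == 1:
        return np.full(years.size, av[0])
    if anchors.kind == "linear":
        vals = np.interp(years, ay, av)
    else:
        vals = PchipInterpolator(ay, av)(np.asarray(years, dtype=float))
        # hold-constant extrapolation
        vals = np.where(years < ay[0], av[0], vals)
        vals = np.where(years > ay[-1], av[-1], vals)
    return vals


def build_pathway_from_anchors(
    anchors: ScenarioAnchors,
    gas: str,
    years: Iterable[int] | None = None,
    label: str = "",
) -> EmissionsPathway:
    """Evaluate anchors on an annual axis (default: the anchor span)."""
    if years is None:
        years = np.arange(anchors.anchors[0][0], anchors.anchors[-1][0] + 1)
    years = np.asarray(list(years), dtype=int)
    return EmissionsPathway(gas, years, _interp_anchors(anchors, years), label=label)


@dataclass(frozen=True)
class ScenarioConfig:
    """Calibration of the stylized 1.5 degC-consistent and BAU pathways.

    CO2 defaults: 35 Gt/yr in 2020 declining at 4.9 %/yr to 2030, net-zero
    2055, -10 Gt/yr floor in 2100, cumulative 2018->net-zero calibrated to
    580 Gt. CH4 defaults: 2050 = 70 Mt/yr = 62 % of the 2010 level
    (112.9 Mt/yr), declining to 55 Mt/yr in 2100; BAU grows 30 % over
    2010-2050 and is held constant after 2050.
    """

    start_year: int = 2000
    end_year: int = 2100
    split_year: int = 2020  # last shared/historical year

    co2_2020: float = 35.0
    co2_decline_rate: float = 0.049  # fractional decline per year, 2020-2030
    co2_net_zero_year: int = 2055
    co2_2100: float = -10.0
    co2_removal_anchor: tuple[int, float] = (2080, -9.0)
    co2_pre2020_growth: float = 0.01  # fractional growth per year before 2020
    cumulative_target_gt: float = 580.0
    budget_start_year: int = 2018

    ch4_2050: float = 70.0
    ch4_drop_by_2050: float = 0.38  # relative to 2010
    ch4_2100: float = 55.0
    bau_growth_by_2050: float = 0.30  # relative to 2010
    bau_post_2050: str = "constant"  # or "linear" continuation

    @property
    def ch4_2010(self) -> float:
        return self.ch4_2050 / (1.0 - self.ch4_drop_by_2050)


def _ch4_shared(config: ScenarioConfig, years: np.ndarray) -> np.ndarray:
    """Pre-split livestock CH4: geometric growth on the BAU 2010-2050 trend."""
    g = (1.0 + config.bau_growth_by_2050) ** (1.0 / 40.0)
    return config.ch4_2010 * g ** (years - 2010.0)


def _co2_mitigation_values(config: ScenarioConfig, mid_value: float) -> tuple[np.ndarray, np.ndarray]:
    years = np.arange(config.start_year, config.end_year + 1)
    v = np.empty(years.size, dtype=float)
    pre = years <= 2020
    v[pre] = config.co2_2020 * (1.0 + config.co2_pre2020_growth) ** (years[pre] - 2020.0)
    decl = (years > 2020) & (years <= 2030)
    v[decl] = config.co2_2020 * (1.0 - config.co2_decline_rate) ** (years[decl] - 2020.0)
    v2030 = config.co2_2020 * (1.0 - config.co2_decline_rate) ** 10
    nz = config.co2_net_zero_year
    mid_year = (2030 + nz) // 2
    tail = ScenarioAnchors(
        [
            (2030, v2030),
            (mid_year, mid_value),
            (nz, 0.0),
            config.co2_removal_anchor,
            (config.end_year, config.co2_2100),
        ]
    )
    post = years > 2030
    v[post] = _interp_anchors(tail, years[post])
    return years, v


def make_mitigation_scenario(
    config: ScenarioConfig | None = None,
) -> tuple[EmissionsPathway, EmissionsPathway]:
    """Stylized 1.5 degC-consistent (net CO2, livestock CH4) pathway pair.

    The free mid-anchor of the 2030->net-zero CO2 segment is calibrated by a
    bracketed root-find so that the trapezoidal cumulative total from
    ``budget_start_year`` to net-zero equals ``cumulative_target_gt``.
    """
    from .budget import cumulative_to_net_zero  # local import, avoids cycle at import time

    config = config or ScenarioConfig()
    v2030 = config.co2_2020 * (1.0 - config.co2_decline_rate) ** 10

    def resid(mid: float) -> float:
        years, v = _co2_mitigation_values(config, mid)
        p = EmissionsPathway("co2_net", years, v)
        return cumulative_to_net_zero(p, config.budget_start_year) - config.cumulative_target_gt

    lo, hi = 0.05 * v2030, 0.98 * v2030
    if resid(lo) * resid(hi) > 0:
        raise ValueError("cumulative CO2 target unreachable within the pathway family")
    mid = brentq(resid, lo, hi, xtol=1e-10)
    years, v = _co2_mitigation_values(config, mid)
    co2 = EmissionsPathway("co2_net", years, v, label="1.5C-consistent")

    shared_years = years[years <= config.split_year]
    ch4_shared = _ch4_shared(config, shared_years)
    future = ScenarioAnchors(
        [
            (config.split_year, float(ch4_shared[-1])),
            (2050, config.ch4_2050),
            (config.end_year, config.ch4_2100),
        ]
    )
    fy = years[years > config.split_year]
    ch4 = EmissionsPathway(
        "ch4_livestock",
        years,
        np.concatenate([ch4_shared, _interp_anchors(future, fy)]),
        label="1.5C-consistent",
    )
    if np.any(ch4.values < 0):
        raise ValueError("configuration produced negative CH4 emissions")
    return co2, ch4


def make_bau_livestock_ch4(config: ScenarioConfig | None = None) -> EmissionsPathway:
    """Business-as-usual livestock CH4: +30 % by 2050 relative to 2010.

    Identical to the mitigation scenario's CH4 up to the split year (shared
    history), geometric growth to 2050, then held constant (default) or
    continued linearly.
    """
    config = config or ScenarioConfig()
    years = np.arange(config.start_year, config.end_year + 1)
    v = _ch4_shared(config, years)
    v2050 = config.ch4_2010 * (1.0 + config.bau_growth_by_2050)
    v[years >= 2050] = v2050  # pin 2050 to exactly 1.3x the 2010 level
    if config.bau_post_2050 == "constant":
        pass
    elif config.bau_post_2050 == "linear":
        slope = v2050 - _ch4_shared(config, np.array([2049.0]))[0]
        post = years > 2050
        v[post] = v2050 + slope * (years[post] - 2050)
    else:
        raise ValueError(f"unknown post-2050 rule {config.bau_post_2050!r}")
    return EmissionsPathway("ch4_livestock", years, v, label="BAU")


def historical_backdrop(
    gas: str, config: ScenarioConfig | None = None, start_year: int = 1850
) -> EmissionsPathway:
    """Stylized global emissions from ``start_year`` to the split year.

    A documented approximation (exponential growth joining the scenario's
    shared pre-split segment at its start year), used only for legacy-warming
    displays — never for marginal quantities. CO2 grows from 0.2 Gt/yr in
    1850; livestock CH4 from 30 Mt/yr.
    """
    config = config or ScenarioConfig()
    years = np.arange(start_year, config.split_year + 1)
    if gas == "co2_net":
        v0, vj = 0.2, config.co2_2020 * (1.0 + config.co2_pre2020_growth) ** (
            config.start_year - 2020.0
        )
        join = config.start_year
        early = v0 * (vj / v0) ** ((years - start_year) / (join - start_year))
        modern = config.co2_2020 * (1.0 + config.co2_pre2020_growth) ** (
            np.asarray(years, float) - 2020.0
        )
    elif gas == "ch4_livestock":
        v0, vj = 30.0, _ch4_shared(config, np.array([float(config.start_year)]))[0]
        join = config.start_year
        early = v0 * (vj / v0) ** ((years - start_year) / (join - start_year))
        modern = _ch4_shared(config, np.asarray(years, float))
    else:
        raise ValueError(f"unknown gas {gas!r}")
    values = np.where(years < join, early, modern)
    return EmissionsPathway(gas, years, values, label="historical (stylized)")


# ---------------------------------------------------------------------------
# IAMC-style wide CSV I/O

_IAMC_INDEX = ["Model", "Scenario", "Region", "Variable", "Unit"]


def write_iamc_csv(
    pathways: Sequence[EmissionsPathway],
    path: str | Path,
    model: str = "herdclim",
    region: str = "World",
) -> None:
    """Write pathways as one IAMC wide CSV (one row per pathway)."""
    rows = []
    for p in pathways:
        variable, unit = GAS_UNITS[p.gas]
        row = {
            "Model": model,
            "Scenario": p.label or p.gas,
            "Region": region,
            "Variable": variable,
            "Unit": unit,
        }
        row.update({int(y): v for y, v in zip(p.years, p.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_iamc_csv(path: str | Path) -> list[EmissionsPathway]:
    """Read an IAMC wide CSV; validates units and year contiguity."""
    df = pd.read_csv(path)
    missing = [c for c in _IAMC_INDEX if c not in df.columns]
    if missing:
        raise ValueError(f"not an IAMC CSV, missing columns {missing}")
    year_cols = [c for c in df.columns if str(c).strip().isdigit()]
    if not year_cols:
        raise ValueError("no year columns found")
    var_to_gas = {v[0]: g for g, v in GAS_UNITS.items()}
    out: list[EmissionsPathway] = []
    for _, row in df.iterrows():
        gas = var_to_gas.get(row["Variable"])
        if gas is None:
            raise ValueError(f"unknown variable {row['Variable']!r}")
        expected_unit = GAS_UNITS[gas][1]
        if row["Unit"] != expected_unit:
            raise ValueError(
                f"unit mismatch for {gas}: got {row['Unit']!r}, expected {expected_unit!r}"
            )
        series = row[year_cols].astype(float).dropna()
        years = np.array([int(c) for c in series.index])
        order = np.argsort(years)
        years = years[order]
        if years.size > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("non-contiguous years in IAMC file")
        out.append(
            EmissionsPathway(gas, years, series.to_numpy()[order], label=str(row["Scenario"]))
        )
    return out


def data_path(name: str) -> Path:
    """Path to a bundled data file (fixtures, default parameter/config files)."""
    return Path(importlib.resources.files("herdclim") / "data" / name)
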