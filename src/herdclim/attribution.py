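"""Marginal vs legacy warming decomposition.

*Marginal warming* is the warming an additional set of (future) emissions
causes relative to their absence, all else equal: the temperature difference
between the full pathway and the same pathway zeroed after a split year.
*Legacy warming* is the warming attributable to emissions up to the split
year alone. In linearized CO2-forcing mode the decomposition is exact:
total = legacy + marginal at every year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emulator import TemperatureSeries, warming_from_emissions
from .params import EmulatorParams
from .scenarios import EmissionsPathway

__all__ = [
    "AttributionResult",
    "marginal_warming",
    "legacy_warming",
    "attribute",
    "warming_share_product",
]

DEFAULT_SPLIT_YEAR = 2020
DEFAULT_REPORT_YEARS = (2050, 2100)


@dataclass(frozen=True)
class AttributionResult:
    """Total/legacy/marginal warming for one emissions component.

    ``legacy_is_stylized`` flags results that depend on the stylized
    historical backdrop fixture; marginal values never do.
    """

    component: str
    split_year: int
    total: TemperatureSeries
    legacy: TemperatureSeries
    marginal: TemperatureSeries
    summary: dict[str, float] = field(default_factory=dict)
    legacy_is_stylized: bool = False


def marginal_warming(
    pathway: EmissionsPathway,
    split_year: int = DEFAULT_SPLIT_YEAR,
    params: EmulatorParams | None = None,
) -> TemperatureSeries:
    """Warming caused by emissions after ``split_year``.

    Computed as warming(full) - warming(zeroed after split); in linearized
    mode this equals the warming of the future-only emissions.
    """
    params = params or EmulatorParams()
    if not pathway.years[0] <= split_year <= pathway.years[-1]:
        raise ValueError(f"split year {split_year} outside pathway axis")
    full = warming_from_emissions(pathway, params)
    past = warming_from_emissions(pathway.zeroed_after(split_year), params)
    return TemperatureSeries(full.years, full.values - past.values, unit="degC")


def legacy_warming(
    history: EmissionsPathway,
    end_year: int = 2100,
    params: EmulatorParams | None = None,
) -> TemperatureSeries:
    """Warming from historical emissions alone, extended with zeros.

    For CH4 the legacy signal decays toward zero within decades of the split
    (only the thermal tail remains); for CO2 the persistent airborne fraction
    keeps it elevated.
    """
    params = params or EmulatorParams()
    return warming_from_emissions(history.extended_to(end_year), params)


def attribute(
    pathway: EmissionsPathway,
    split_year: int = DEFAULT_SPLIT_YEAR,
    params: EmulatorParams | None = None,
    report_years: tuple[int, ...] = DEFAULT_REPORT_YEARS,
    legacy_is_stylized: bool = False,
) -> AttributionResult:
    """Decompose a pathway's warming into legacy (<= split) and marginal parts."""
    params = params or EmulatorParams()
    total = warming_from_emissions(pathway, params)
    legacy = warming_from_emissions(pathway.zeroed_after(split_year), params)
    marginal = TemperatureSeries(total.years, total.values - legacy.values, unit="degC")
    summary = {}
    for y in report_years:
        if pathway.years[0] <= y <= pathway.years[-1]:
            summary[f"marginal_{y}"] = marginal.value_at(y)
            summary[f"legacy_{y}"] = legacy.value_at(y)
            summary[f"total_{y}"] = total.value_at(y)
    return AttributionResult(
        component=pathway.label or pathway.gas,
        split_year=split_year,
        total=total,
        legacy=legacy,
        marginal=marginal,
        summary=summary,
        legacy_is_stylized=legacy_is_stylized,
    )


def warming_share_product(forcing_share: float, source_share: float) -> float:
    """Percent of anthropogenic warming attributable to a source.

    Product of the gas's share of total forcing and the source's share of the
    gas's emissions, e.g. CH4's ~40 % of forcing times livestock's ~30 % of
    CH4 emissions gives ~12 %.
    """
    for name, x in (("forcing_share", forcing_share), ("source_share", source_share)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return 100.0 * forcing_share * source_share
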