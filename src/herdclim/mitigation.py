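"""Livestock CH4 mitigation-potential accounting.

Adoption-times-efficacy arithmetic over a 2010 emissions table disaggregated
by production system (feedlot/TMR, mixed/intensive grazing, extensive) and
income group, grown by a factor (default 1.3) to a 2050 baseline:

    potential = sum over applicable rows of
                emissions_2010 * growth * efficacy * adoption

A computed potential can be coupled into a business-as-usual CH4 pathway as a
linearly ramped abatement wedge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scenarios import EmissionsPathway, data_path

__all__ = [
    "SYSTEMS",
    "INCOME_GROUPS",
    "LivestockEmissionsTable",
    "Intervention",
    "load_emissions_table",
    "load_interventions",
    "baseline_2050",
    "mitigation_potential",
    "apply_to_pathway",
]

SYSTEMS = ("feedlot", "mixed", "extensive")
INCOME_GROUPS = ("high", "upper_middle", "lower_middle", "low")


@dataclass(frozen=True)
class LivestockEmissionsTable:
    """2010 livestock CH4 emissions (Mt/yr) by production system x income group."""

    df: pd.DataFrame  # columns: system, income_group, mt_ch4_2010

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        required = {"system", "income_group", "mt_ch4_2010"}
        if not required.issubset(df.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if not set(df["system"]).issubset(SYSTEMS):
            raise ValueError(f"unknown systems {set(df['system']) - set(SYSTEMS)}")
        if not set(df["income_group"]).issubset(INCOME_GROUPS):
            raise ValueError(
                f"unknown income groups {set(df['income_group']) - set(INCOME_GROUPS)}"
            )
        if df.duplicated(["system", "income_group"]).any():
            raise ValueError("duplicate (system, income_group) rows")
        if (df["mt_ch4_2010"] < 0).any():
            raise ValueError("emissions must be >= 0")
        object.__setattr__(self, "df", df)

    @property
    def total(self) -> float:
        return float(self.df["mt_ch4_2010"].sum())


@dataclass(frozen=True)
class Intervention:
    """One mitigation technology and its adoption schedule.

    ``adoption`` maps income group -> adoption fraction within the systems the
    intervention applies to; income groups not listed get zero adoption.
    """

    name: str
    systems: tuple[str, ...]
    efficacy: float
    adoption: Mapping[str, float]
    growth: float = 1.3

    def __post_init__(self):
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("efficacy must lie in [0, 1]")
        if any(not 0.0 <= a <= 1.0 for a in self.adoption.values()):
            raise ValueError("adoption fractions must lie in [0, 1]")
        if self.growth <= 0:
            raise ValueError("growth factor must be positive")
        unknown = set(self.systems) - set(SYSTEMS)
        if unknown:
            raise ValueError(f"unknown systems {unknown}")


def load_emissions_table(path: str | Path | None = None) -> LivestockEmissionsTable:
    """Load an emissions table CSV; default is the bundled synthetic fixture.

    The bundled table is NOT real GLEAM output: its feedlot total is
    back-calibrated so that a 30 % inhibitor at full feedlot adoption yields
    0.8 Mt in 2050, and the remaining cells are invented plausible values.
    Supply a CSV extracted from GLEAM for real analyses.
    """
    path = path or data_path("gleam_2010_synthetic.csv")
    return LivestockEmissionsTable(pd.read_csv(path))


def load_interventions(path: str | Path | None = None) -> list[Intervention]:
    """Load interventions from YAML; default is the bundled schedule set."""
    path = path or data_path("interventions.yaml")
    raw = yaml.safe_load(Path(path).read_text())
    return [
        Intervention(
            name=item["name"],
            systems=tuple(item["systems"]),
            efficacy=float(item["efficacy"]),
            adoption={k: float(v) for k, v in item["adoption"].items()},
            growth=float(item.get("growth", 1.3)),
        )
        for item in raw
    ]


def baseline_2050(table: LivestockEmissionsTable, growth: float = 1.3) -> LivestockEmissionsTable:
    """Scale every row by the growth factor to approximate 2050 baseline emissions."""
    df = table.df.copy()
    df["mt_ch4_2010"] = df["mt_ch4_2010"] * growth
    return LivestockEmissionsTable(df)


def mitigation_potential(table: LivestockEmissionsTable, intervention: Intervention) -> float:
    """Global 2050 mitigation potential of one intervention, Mt CH4/yr."""
    df = table.df
    total = 0.0
    applicable_incomes = set()
    for _, row in df.iterrows():
        if row["system"] not in intervention.systems:
            continue
        applicable_incomes.add(row["income_group"])
        adoption = intervention.adoption.get(row["income_group"], 0.0)
        total += row["mt_ch4_2010"] * intervention.growth * intervention.efficacy * adoption
    orphan = set(intervention.adoption) - applicable_incomes
    if orphan:
        warnings.warn(
            f"{intervention.name}: adoption specified for income groups with no "
            f"applicable rows, ignored: {sorted(orphan)}",
            stacklevel=2,
        )
    return float(total)


def apply_to_pathway(
    bau_ch4: EmissionsPathway,
    potential: float,
    ramp_start: int = 2025,
    full_year: int = 2050,
) -> EmissionsPathway:
    """Subtract a linearly ramped abatement wedge from a CH4 pathway.

    The wedge is zero before ``ramp_start``, grows linearly to ``potential``
    at ``full_year`` and is held constant after. Results are clipped at zero
    with a warning if the wedge exceeds the pathway.
    """
    if potential < 0:
        raise ValueError("potential must be >= 0")
    years = bau_ch4.years
    ramp = np.clip((years - ramp_start) / (full_year - ramp_start), 0.0, 1.0)
    wedge = potential * ramp
    v = bau_ch4.values - wedge
    if np.any(v < 0):
        warnings.warn("abatement wedge exceeds the pathway; clipping at zero", stacklevel=2)
        v = np.maximum(v, 0.0)
    return replace(bau_ch4, values=v, label=f"{bau_ch4.label}|abated")
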