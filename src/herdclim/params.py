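"""Emulator coefficients: gas cycles, radiative forcing and thermal response.

Defaults are an AR5-era median calibration of the standard reduced-complexity
emulator chain (IRF carbon cycle, single-lifetime CH4 box, two-mode energy
balance), documented in docs/methods.md. Everything is configurable from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = ["GasCycleParams", "ThermalParams", "EmulatorParams", "load_params", "save_params"]


@dataclass(frozen=True)
class GasCycleParams:
    """Carbon-cycle / CH4-box and forcing coefficients.

    CO2 impulse response: a fraction ``co2_a0`` of an emitted pulse remains
    airborne indefinitely; three further fractions decay with e-folding times
    ``co2_tau`` (years). Fractions must sum to 1. CH4 follows a single box
    with perturbation lifetime ``ch4_lifetime``. ``ch4_indirect`` multiplies
    direct CH4 forcing for tropospheric ozone and stratospheric water vapour.
    """

    co2_a0: float = 0.2173
    co2_a: tuple[float, ...] = (0.2240, 0.2824, 0.2763)
    co2_tau: tuple[float, ...] = (394.4, 36.54, 4.304)
    gt_co2_per_ppm: float = 7.814
    ch4_lifetime: float = 12.0
    mt_ch4_per_ppb: float = 2.75
    co2_forcing_mode: str = "linear"  # "linear" or "log"
    co2_linear_wm2_per_ppm: float = 0.0134
    co2_log_coefficient: float = 5.35  # W/m2 per ln(C/C0)
    co2_reference_ppm: float = 400.0
    ch4_wm2_per_ppb: float = 3.63e-4
    ch4_indirect: float = 1.65

    def __post_init__(self):
        if abs(self.co2_a0 + sum(self.co2_a) - 1.0) > 1e-9:
            raise ValueError("CO2 IRF fractions must sum to 1")
        if len(self.co2_a) != len(self.co2_tau):
            raise ValueError("co2_a and co2_tau must have equal length")
        if any(t <= 0 for t in self.co2_tau) or self.ch4_lifetime <= 0:
            raise ValueError("all lifetimes must be positive")
        if self.ch4_indirect < 1.0:
            raise ValueError("indirect-effects multiplier must be >= 1")
        if self.co2_reference_ppm <= 0:
            raise ValueError("reference concentration must be positive")
        if self.co2_forcing_mode not in ("linear", "log"):
            raise ValueError(f"unknown CO2 forcing mode {self.co2_forcing_mode!r}")


@dataclass(frozen=True)
class ThermalParams:
    """Two-mode energy-balance response: T(t) = sum_j (q_j/d_j) e^(-t/d_j) * F.

    ``q`` in K per (W/m2) (their sum is the equilibrium warming per unit
    forcing), ``d`` the fast/slow response times in years. Defaults keep the
    AR5 metric-convention mode structure (d = 8.4/409.5 yr, q1:q2 ratio) but
    are scaled so the equilibrium climate sensitivity is 3.0 K per CO2
    doubling (sum q = 0.811 K/(W/m2) with F_2x = 3.7 W/m2), the median of the
    probabilistic MAGICC ensembles this emulator approximates.
    """

    q: tuple[float, float] = (0.483, 0.328)
    d: tuple[float, float] = (8.4, 409.5)

    def __post_init__(self):
        if any(x <= 0 for x in self.q + self.d):
            raise ValueError("q and d must be positive")
        if not self.d[0] < self.d[1]:
            raise ValueError("response times must be ordered d1 < d2")


@dataclass(frozen=True)
class EmulatorParams:
    gas: GasCycleParams = field(default_factory=GasCycleParams)
    thermal: ThermalParams = field(default_factory=ThermalParams)

    def with_co2_mode(self, mode: str) -> "EmulatorParams":
        return replace(self, gas=replace(self.gas, co2_forcing_mode=mode))


def _tuples(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and v is not None else v for k, v in d.items()}


def load_params(path: str | Path | None = None) -> EmulatorParams:
    """Load emulator parameters from YAML; missing fields keep their defaults."""
    if path is None:
        return EmulatorParams()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gas = _tuples(raw.get("gas", {}), ("co2_a", "co2_tau"))
    thermal = _tuples(raw.get("thermal", {}), ("q", "d"))
    return EmulatorParams(gas=GasCycleParams(**gas), thermal=ThermalParams(**thermal))


def save_params(params: EmulatorParams, path: str | Path) -> None:
    d = {"gas": asdict(params.gas), "thermal": asdict(params.thermal)}

    def _listify(obj):
        if isinstance(obj, dict):
            return {k: _listify(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(_listify(d), sort_keys=False))
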