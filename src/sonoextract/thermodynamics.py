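"""Extraction thermodynamics: equilibrium constant, Van't Hoff regression,
and the Gibbs-energy series.

The extraction equilibrium constant at each temperature is the ratio of
extracted to remaining extractable solute, K_eq = C_s / (C_max - C_s).
Van't Hoff's relation ln K_eq = -dH/(R T) + dS/R yields the standard
enthalpy and entropy of extraction from an OLS line of ln K_eq on 1/T, and
dG(T) = dH - T dS (equivalently -R T ln K_eq on the isotherm route).
Positive dH and dS with negative dG across the working range characterise
an endothermic, entropy-driven, spontaneous process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .core_data import (
    GAS_CONSTANT,
    DomainError,
    FitQuality,
    ValidationError,
    celsius_to_kelvin,
    goodness_of_fit,
)

__all__ = [
    "ThermoResult",
    "equilibrium_constant",
    "vant_hoff_fit",
    "gibbs_energy",
    "gibbs_from_keq",
    "thermo_analysis",
]


@dataclass
class ThermoResult:
    """Thermodynamic summary: dH (J/mol), dS (J/(mol K)), dG(T) series (J/mol)."""

    delta_h: float
    delta_s: float
    delta_g_series: list[tuple[float, float]]  # (T kelvin, dG J/mol)
    keq_series: list[tuple[float, float]]  # (T kelvin, K_eq)
    c_max: float | None
    quality: FitQuality

    def __post_init__(self) -> None:
        if any(keq <= 0 for _, keq in self.keq_series):
            raise ValidationError("all K_eq must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return {
            "delta_h": self.delta_h,
            "delta_s": self.delta_s,
            "delta_g_series": [list(p) for p in self.delta_g_series],
            "keq_series": [list(p) for p in self.keq_series],
            "c_max": self.c_max,
            "quality": self.quality.to_dict(),
        }


def equilibrium_constant(cs: float, c_max: float) -> float:
    """K_eq = C_s / (C_max - C_s): extracted over remaining extractable."""
    if cs <= 0:
        raise DomainError("cs must be > 0")
    if cs >= c_max:
        raise DomainError(
            f"K_eq undefined: cs ({cs}) must be below c_max ({c_max}) "
            "(complete extraction)"
        )
    return cs / (c_max - cs)


def vant_hoff_fit(
    keq_series: Sequence[tuple[float, float]],
    gas_constant: float = GAS_CONSTANT,
) -> tuple[float, float, FitQuality]:
    """OLS of ln K_eq on 1/T: returns (dH J/mol, dS J/(mol K), quality).

    ``keq_series`` holds (temperature kelvin, K_eq) pairs.  The slope gives
    dH = -slope * R and the intercept dS = intercept * R.
    """
    arr = np.asarray(keq_series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("keq_series must be (temperature K, K_eq) pairs")
    t_kelvin, keq = arr[:, 0], arr[:, 1]
    if np.any(t_kelvin <= 0):
        raise ValidationError("temperatures must be > 0 K")
    if np.any(keq <= 0):
        raise ValidationError("all K_eq must be > 0")
    if np.unique(t_kelvin).size < 2:
        raise ValidationError("Van't Hoff fit needs >= 2 distinct temperatures")
    inv_t = 1.0 / t_kelvin
    ln_keq = np.log(keq)
    slope, intercept = np.polyfit(inv_t, ln_keq, 1)
    predicted = slope * inv_t + intercept
    quality = (
        goodness_of_fit(ln_keq, predicted)
        if np.unique(ln_keq).size > 1
        else FitQuality(1.0, 0.0, 0.0, ln_keq.size)
    )
    return float(-slope * gas_constant), float(intercept * gas_constant), quality


def gibbs_energy(delta_h: float, delta_s: float, temperature_k: float) -> float:
    """dG = dH - T dS, all in J/mol with T in kelvin."""
    if temperature_k <= 0:
        raise ValidationError("temperature must be > 0 K")
    return delta_h - temperature_k * delta_s


def gibbs_from_keq(
    keq: float, temperature_k: float, gas_constant: float = GAS_CONSTANT
) -> float:
    """Gibbs isotherm dG = -R T ln K_eq, J/mol."""
    if keq <= 0:
        raise DomainError("K_eq must be > 0")
    if temperature_k <= 0:
        raise ValidationError("temperature must be > 0 K")
    return -gas_constant * temperature_k * np.log(keq)


def thermo_analysis(
    cs_by_temperature: Sequence[tuple[float, float]],
    c_max: float,
    gas_constant: float = GAS_CONSTANT,
) -> ThermoResult:
    """Full thermodynamic chain from saturation concentrations.

    ``cs_by_temperature`` holds (temperature degC, C_s) pairs; a single
    global C_max converts each C_s into K_eq, the Van't Hoff line gives
    dH and dS, and dG(T) = dH - T dS is evaluated on the same grid.
    """
    keq_series = [
        (celsius_to_kelvin(t_c), equilibrium_constant(cs, c_max))
        for t_c, cs in cs_by_temperature
    ]
    delta_h, delta_s, quality = vant_hoff_fit(keq_series, gas_constant)
    delta_g_series = [
        (t_k, gibbs_energy(delta_h, delta_s, t_k)) for t_k, _ in keq_series
    ]
    return ThermoResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g_series=delta_g_series,
        keq_series=keq_series,
        c_max=c_max,
        quality=quality,
    )
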