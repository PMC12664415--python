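"""Assay-side quantification: standard-curve calibration, phenolic/flavonoid
content, and DPPH radical-scavenging percent inhibition.

Total phenolic content (Folin-Ciocalteu, gallic-acid equivalents) and total
flavonoid content (AlCl3 method, catechin equivalents) share the same form:
the analyte concentration C (mg/L) read off a linear standard curve is scaled
by extract volume V (L) and dilution factor D_f and normalised by sample dry
weight W (g), giving mg equivalents per g dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core_data import (
    DomainError,
    ValidationError,
    goodness_of_fit,
    warn,
)

__all__ = [
    "Calibration",
    "AssaySample",
    "fit_calibration",
    "content_from_assay",
    "dpph_inhibition",
    "TPC_DILUTION_FACTOR",
    "TFC_DILUTION_FACTOR",
]

#: Default dilution factor for the total-phenolic (Folin-Ciocalteu) assay.
TPC_DILUTION_FACTOR: float = 20.0
#: Default dilution factor for the total-flavonoid (AlCl3) assay.
TFC_DILUTION_FACTOR: float = 40.0


@dataclass(frozen=True)
class Calibration:
    """A linear standard curve, absorbance = slope * C + intercept.

    Fitted forward (absorbance on concentration) and inverted analytically
    when a sample concentration is needed; ``c_min``/``c_max`` record the
    standard range so out-of-range samples can be flagged.
    """

    slope: float
    intercept: float
    r_squared: float
    analyte: str = "gallic-acid"
    c_min: float | None = None
    c_max: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("calibration slope must be non-zero")

    def concentration(self, absorbance: float) -> float:
        """Invert the standard curve: C = (A - intercept)/slope, mg/L."""
        return (absorbance - self.intercept) / self.slope

    def to_dict(self) -> dict[str, Any]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "analyte": self.analyte,
            "c_min": self.c_min,
            "c_max": self.c_max,
        }


@dataclass(frozen=True)
class AssaySample:
    """One spectrophotometric measurement of an extract aliquot."""

    absorbance: float
    blank_absorbance: float = 0.0
    extract_volume: float = 0.08  # L
    dilution_factor: float = TPC_DILUTION_FACTOR
    dry_weight: float = 4.0  # g

    def __post_init__(self) -> None:
        if self.extract_volume <= 0:
            raise ValidationError("extract_volume must be > 0")
        if self.dry_weight <= 0:
            raise ValidationError("dry_weight must be > 0")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")


def fit_calibration(
    standards: Sequence[tuple[float, float]], analyte: str = "gallic-acid"
) -> Calibration:
    """Ordinary-least-squares standard curve from (concentration, absorbance) pairs."""
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("need >= 2 (concentration, absorbance) pairs")
    conc, absorb = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 2:
        raise ValidationError("standards must span >= 2 distinct concentrations")
    slope, intercept = np.polyfit(conc, absorb, 1)
    predicted = slope * conc + intercept
    if np.allclose(absorb, absorb[0]):
        r_squared = 1.0 if np.allclose(predicted, absorb) else 0.0
    else:
        r_squared = goodness_of_fit(absorb, predicted).r_squared
    return Calibration(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        analyte=analyte,
        c_min=float(conc.min()),
        c_max=float(conc.max()),
    )


def content_from_assay(calibration: Calibration, sample: AssaySample) -> float:
    """mg equivalents per g dry weight: C * V * D_f / W.

    The inferred concentration C comes from inverting the standard curve.
    Negative C (absorbance below the intercept) is reported as computed with
    a warning, never clamped; same for samples outside the calibrated range.
    """
    c = calibration.concentration(sample.absorbance)
    if calibration.c_min is not None and not (
        calibration.c_min <= c <= (calibration.c_max or np.inf)
    ):
        warn(
            f"inferred concentration {c:.4g} mg/L outside calibration range "
            f"[{calibration.c_min:g}, {calibration.c_max:g}] mg/L"
        )
    if c < 0:
        warn(f"negative inferred concentration {c:.4g} mg/L (absorbance below intercept)")
    return c * sample.extract_volume * sample.dilution_factor / sample.dry_weight


def dpph_inhibition(blank_absorbance: float, sample_absorbance: float) -> float:
    """DPPH radical-scavenging activity, percent inhibition.

    100 * (A_blank - A_sample) / A_blank; values outside [0, 100] are
    reported with a warning (sample more absorbing than the blank).
    """
    if blank_absorbance <= 0:
        raise DomainError("blank absorbance must be > 0")
    pct = 100.0 * (blank_absorbance - sample_absorbance) / blank_absorbance
    if pct < 0 or pct > 100:
        warn(f"DPPH inhibition {pct:.4g}% outside [0, 100]")
    return pct
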