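"""Pseudo-second-order (PSO) extraction kinetics.

The dissolution rate is taken proportional to the squared distance from
saturation, dC/dt = k (C_s - C_t)^2 with C(0) = 0, whose solution is

    C_t = C_s^2 k t / (1 + C_s k t).

The model linearizes as t/C_t = 1/(k C_s^2) + t/C_s, so an ordinary
least-squares line of t/C_t on t yields slope = 1/C_s and intercept = 1/h
with h = k C_s^2 the initial extraction rate.  The temperature dependence
of k is described by the Arrhenius law k = k0 exp(-Ea/(R T)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core_data import (
    GAS_CONSTANT,
    ExtractionCurve,
    FitError,
    FitQuality,
    ValidationError,
    celsius_to_kelvin,
    goodness_of_fit,
    warn,
)

__all__ = [
    "PSOFit",
    "ArrheniusFit",
    "pso_predict",
    "fit_pso_linearized",
    "initial_rate",
    "fit_arrhenius",
]


@dataclass(frozen=True)
class PSOFit:
    """Fitted pseudo-second-order parameters for one extraction curve.

    ``cs`` is the saturation (equilibrium) concentration in mg GAE/g d.w.,
    ``k`` the rate constant in g d.w./(mg GAE min), ``h = k cs^2`` the
    initial extraction rate.  ``quality`` is computed on the concentration
    scale (observed C_t against the model curve), not the linearized scale.
    """

    cs: float
    k: float
    h: float
    quality: FitQuality
    temperature: float
    method_label: str = "UAE"
    cs_se: float | None = None
    k_se: float | None = None

    def __post_init__(self) -> None:
        if self.cs <= 0 or self.k <= 0:
            raise FitError(f"inadmissible PSO parameters cs={self.cs}, k={self.k}")
        if abs(self.h - self.k * self.cs**2) > 1e-10 * abs(self.h):
            raise ValidationError("h must equal k*cs^2")

    def to_dict(self) -> dict[str, Any]:
        return {
            "cs": self.cs,
            "k": self.k,
            "h": self.h,
            "cs_se": self.cs_se,
            "k_se": self.k_se,
            "temperature": self.temperature,
            "method_label": self.method_label,
            "quality": self.quality.to_dict(),
        }


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters: activation energy Ea (J/mol), prefactor k0."""

    ea: float
    k0: float
    quality: FitQuality

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise FitError("Arrhenius prefactor k0 must be > 0")

    def rate_constant(self, temperature_c: float) -> float:
        """k(T) = k0 exp(-Ea / (R T)) at the given Celsius temperature."""
        t_kelvin = celsius_to_kelvin(temperature_c)
        return self.k0 * np.exp(-self.ea / (GAS_CONSTANT * t_kelvin))

    def to_dict(self) -> dict[str, Any]:
        return {"ea": self.ea, "k0": self.k0, "quality": self.quality.to_dict()}


def pso_predict(
    cs: float, k: float, times: Sequence[float] | float
) -> np.ndarray | float:
    """Concentration series of the pseudo-second-order model.

    C_t = cs^2 k t / (1 + cs k t); zero at t = 0, strictly increasing,
    saturating at ``cs``.
    """
    if cs <= 0 or k <= 0:
        raise ValidationError(f"cs and k must be > 0 (got cs={cs}, k={k})")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be non-negative")
    out = cs**2 * k * t / (1.0 + cs * k * t)
    return float(out) if out.ndim == 0 else out


def initial_rate(k: float, cs: float) -> float:
    """Initial extraction rate h = k cs^2, mg GAE/(g d.w. min)."""
    if k <= 0 or cs <= 0:
        raise ValidationError(f"k and cs must be > 0 (got k={k}, cs={cs})")
    return k * cs**2


def fit_pso_linearized(
    curve: ExtractionCurve,
    method_label: str | None = None,
    refine: bool = False,
) -> PSOFit:
    """Fit the PSO model by the linearized t/C_t-versus-t regression.

    Points with C_t <= 0 at t > 0 (and the t = 0 point) are excluded from
    the linearized regression; at least three usable points are required.
    Standard errors of cs and k are propagated from the OLS slope/intercept
    covariance by the delta method.  With ``refine=True`` the linearized
    estimate seeds a direct nonlinear least-squares fit of the model curve.
    """
    usable = (curve.times > 0) & (curve.concentrations > 0)
    dropped = (curve.times > 0) & (curve.concentrations <= 0)
    if dropped.any():
        warn(f"{int(dropped.sum())} non-positive concentration point(s) excluded from PSO fit")
    t = curve.times[usable]
    c = curve.concentrations[usable]
    if t.size < 3:
        raise FitError(f"PSO fit needs >= 3 usable points, got {t.size}")

    y = t / c
    (slope, intercept), cov = np.polyfit(t, y, 1, cov=True)
    if slope <= 0 or intercept <= 0:
        raise FitError(
            "pseudo-second-order model inadequate: non-positive slope or intercept "
            f"(slope={slope:.4g}, intercept={intercept:.4g})"
        )
    cs = 1.0 / slope
    k = slope**2 / intercept
    # Delta method on g(slope, intercept).
    var_s, var_i = cov[0, 0], cov[1, 1]
    cov_si = cov[0, 1]
    cs_se = float(np.sqrt(var_s) / slope**2)
    dk_ds = 2 * slope / intercept
    dk_di = -(slope**2) / intercept**2
    k_var = dk_ds**2 * var_s + dk_di**2 * var_i + 2 * dk_ds * dk_di * cov_si
    k_se = float(np.sqrt(max(k_var, 0.0)))

    if refine:
        try:
            popt, pcov = curve_fit(
                lambda tt, cs_, k_: cs_**2 * k_ * tt / (1 + cs_ * k_ * tt),
                t,
                c,
                p0=[cs, k],
                maxfev=10000,
            )
            cs, k = float(popt[0]), float(popt[1])
            perr = np.sqrt(np.diag(pcov))
            cs_se, k_se = float(perr[0]), float(perr[1])
        except RuntimeError as exc:  # pragma: no cover - rare
            raise FitError(f"nonlinear PSO refinement failed: {exc}") from exc
        if cs <= 0 or k <= 0:
            raise FitError("nonlinear PSO refinement left the admissible region")

    quality = goodness_of_fit(c, pso_predict(cs, k, t))
    return PSOFit(
        cs=cs,
        k=k,
        h=initial_rate(k, cs),
        quality=quality,
        temperature=curve.temperature,
        method_label=method_label or curve.method,
        cs_se=cs_se,
        k_se=k_se,
    )


def fit_arrhenius(
    rate_constants: Sequence[tuple[float, float]],
    gas_constant: float = GAS_CONSTANT,
) -> ArrheniusFit:
    """Arrhenius regression of ln k on 1/T.

    ``rate_constants`` is a sequence of (temperature degC, k) pairs; the
    slope of the OLS line gives Ea = -slope * R and the intercept k0.
    Over a range where k is non-monotone in T (e.g. thermal degradation at
    high temperature) the law only holds on the ascending branch — pass
    that subset explicitly.
    """
    arr = np.asarray(rate_constants, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("rate_constants must be (temperature, k) pairs")
    temps_c, ks = arr[:, 0], arr[:, 1]
    if np.any(ks <= 0):
        raise ValidationError("all rate constants must be > 0")
    if np.unique(temps_c).size < 2:
        raise ValidationError("Arrhenius fit needs >= 2 distinct temperatures")
    inv_t = 1.0 / celsius_to_kelvin(temps_c)
    ln_k = np.log(ks)
    slope, intercept = np.polyfit(inv_t, ln_k, 1)
    predicted = slope * inv_t + intercept
    quality = (
        goodness_of_fit(ln_k, predicted)
        if np.unique(ln_k).size > 1
        else FitQuality(1.0, 0.0, 0.0, ln_k.size)
    )
    return ArrheniusFit(
        ea=float(-slope * gas_constant), k0=float(np.exp(intercept)), quality=quality
    )
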