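"""Crank sphere-diffusion model: series solution, De fitting, and a
residual-resampling bootstrap for its uncertainty.

Fick's second law for radial diffusion in a sphere of radius R, with uniform
initial concentration and a constant surface concentration, has the classic
Crank series solution for the volume-averaged unaccomplished ratio

    y(t) = (C_inf - C(t)) / (C_inf - C_0)
         = (6/pi^2) * sum_{n>=1} n^-2 exp(-n^2 pi^2 De t / R^2).

The effective diffusivity De (m^2/s) is estimated by nonlinear least squares
on the y scale under the physical constraint De >= 0.  Internally the fit
works on the well-scaled rate parameter kappa = De/R^2 (1/s) and transforms
back.  Uncertainty comes from a residual-resampling bootstrap: centred
residuals are resampled with replacement onto the fitted curve, kappa is
refit on each pseudo-dataset, and the De* = kappa* R^2 draws provide the
standard error and a 95 % percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core_data import (
    DomainError,
    ExtractionCurve,
    FitError,
    FitQuality,
    ValidationError,
    goodness_of_fit,
    warn,
)

__all__ = [
    "DiffusionFit",
    "BootstrapResult",
    "crank_y",
    "unaccomplished_ratio",
    "fit_de",
    "bootstrap_de",
]

_PI2 = np.pi**2
_BASEL_FACTOR = 6.0 / _PI2


def crank_y(
    de: float,
    radius: float,
    time_seconds: Sequence[float] | float,
    n_terms: int = 10,
) -> np.ndarray | float:
    """Truncated Crank series for the unaccomplished ratio of a sphere.

    y = (6/pi^2) sum_{n=1}^{n_terms} n^-2 exp(-n^2 pi^2 De t / R^2).

    At t = 0 the infinite series sums to 1 (Basel problem); a finite
    truncation undershoots 1 by the series tail.  y is monotone
    non-increasing in both t and De.
    """
    if de < 0:
        raise ValidationError("de must be >= 0")
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    t = np.atleast_1d(np.asarray(time_seconds, dtype=float))
    if np.any(t < 0):
        raise ValidationError("time must be >= 0")
    n = np.arange(1, n_terms + 1, dtype=float)
    kappa = de / radius**2
    # exp(-n^2 pi^2 kappa t): (len(t), n_terms)
    terms = np.exp(-np.outer(t, n**2) * _PI2 * kappa)
    y = _BASEL_FACTOR * terms @ (1.0 / n**2)
    return float(y[0]) if np.ndim(time_seconds) == 0 else y


def _crank_y_kappa(kappa: float, t: np.ndarray, n_terms: int) -> np.ndarray:
    n2 = np.arange(1, n_terms + 1, dtype=float) ** 2
    return _BASEL_FACTOR * np.exp(-np.outer(t, n2) * _PI2 * kappa) @ (1.0 / n2)


def _crank_dy_dkappa(kappa: float, t: np.ndarray, n_terms: int) -> np.ndarray:
    n2 = np.arange(1, n_terms + 1, dtype=float) ** 2
    return -6.0 * (np.exp(-np.outer(t, n2) * _PI2 * kappa) @ np.ones_like(n2)) * t


@dataclass
class DiffusionFit:
    """Fitted effective diffusivity for one y(t) series.

    ``y_series`` holds the fitted (model) unaccomplished-ratio values at the
    observed times; observed values and times are retained so the residual
    bootstrap can rebuild pseudo-datasets.
    """

    de: float
    n_terms: int
    radius: float
    quality: FitQuality
    c_inf: float | None
    c0: float
    y_series: np.ndarray
    times_seconds: np.ndarray = field(repr=False, default=None)
    y_observed: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.de < 0:
            raise ValidationError("de must be >= 0")
        if self.n_terms < 1:
            raise ValidationError("n_terms must be >= 1")

    @property
    def kappa(self) -> float:
        """Rate parameter De/R^2, 1/s."""
        return self.de / self.radius**2

    @property
    def residuals(self) -> np.ndarray:
        return self.y_observed - self.y_series

    def to_dict(self) -> dict[str, Any]:
        return {
            "de": self.de,
            "n_terms": self.n_terms,
            "radius": self.radius,
            "c_inf": self.c_inf,
            "c0": self.c0,
            "quality": self.quality.to_dict(),
            "y_series": self.y_series.tolist(),
        }


@dataclass
class BootstrapResult:
    """Residual-bootstrap uncertainty summary for a De estimate."""

    point_estimate: float
    standard_error: float
    ci_low: float
    ci_high: float
    n_iterations: int
    seed: int | None
    distribution: np.ndarray = field(repr=False, default=None)
    n_failures: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "point_estimate": self.point_estimate,
            "standard_error": self.standard_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "n_failures": self.n_failures,
        }


def unaccomplished_ratio(
    curve: ExtractionCurve, c_inf: float, c0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Transform a concentration curve to (time_seconds, y) for the Crank fit.

    y_i = (C_inf - C_t,i) / (C_inf - C_0); times converted from minutes to
    seconds.  Points with C_t > C_inf (noise above equilibrium, which would
    map outside the model's domain) are dropped with a warning.
    """
    if c_inf <= c0:
        raise ValidationError(f"c_inf ({c_inf}) must exceed c0 ({c0})")
    keep = curve.concentrations <= c_inf
    if not keep.all():
        warn(
            f"{int((~keep).sum())} point(s) with C_t > C_inf dropped from "
            "unaccomplished-ratio series"
        )
    t_seconds = curve.times[keep] * 60.0
    y = (c_inf - curve.concentrations[keep]) / (c_inf - c0)
    return t_seconds, y


def _initial_kappa(t: np.ndarray, y: np.ndarray) -> float:
    """One-term log-linear initial value: ln y ~ ln(6/pi^2) - pi^2 kappa t.

    Uses the tail half of the series where the one-term approximation is
    accurate; falls back to 1e-5 s^-1 if the slope is non-negative.
    """
    tail = slice(t.size // 2, None)
    tt, yy = t[tail], y[tail]
    pos = yy > 0
    if pos.sum() >= 2:
        slope = np.polyfit(tt[pos], np.log(yy[pos]), 1)[0]
        if slope < 0:
            return -slope / _PI2
    return 1e-5


def fit_de(
    y_series: tuple[Sequence[float], Sequence[float]],
    radius: float,
    n_terms: int = 10,
    init_de: float | None = None,
    c_inf: float | None = None,
    c0: float = 0.0,
) -> DiffusionFit:
    """Estimate De by constrained nonlinear least squares on the y scale.

    Parameters
    ----------
    y_series
        Pair (time_seconds, y) of equal-length arrays; y must lie in (0, 1]
        (values outside are rejected with a warning).
    radius
        Particle radius R in metres.
    n_terms
        Series truncation; 10 is accurate for Fourier numbers >= 0.01, a
        single term is biased low at small times.
    init_de
        Optional starting value; by default a one-term log-linear fit on
        the tail provides it.

    The optimizer works on kappa = De/R^2 with the bound kappa >= 0 and
    an analytic Jacobian; the fit quality is reported on the y scale.
    """
    t = np.asarray(y_series[0], dtype=float)
    y = np.asarray(y_series[1], dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("y_series must be a pair of equal-length 1-D arrays")
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    keep = (y > 0) & (y <= 1.0)
    if not keep.all():
        warn(f"{int((~keep).sum())} y value(s) outside (0, 1] rejected from De fit")
        t, y = t[keep], y[keep]
    if t.size < 3:
        raise FitError(f"De fit needs >= 3 usable points, got {t.size}")
    if np.unique(y).size == 1:
        raise ValidationError("all y values identical; De not identifiable")

    kappa0 = init_de / radius**2 if init_de is not None else _initial_kappa(t, y)
    result = least_squares(
        lambda p: _crank_y_kappa(p[0], t, n_terms) - y,
        x0=[max(kappa0, 0.0)],
        jac=lambda p: _crank_dy_dkappa(p[0], t, n_terms)[:, np.newaxis],
        bounds=(0.0, np.inf),
        method="trf",
    )
    if not result.success:
        raise FitError(f"De fit did not converge: {result.message}")
    kappa_hat = float(result.x[0])
    fitted = _crank_y_kappa(kappa_hat, t, n_terms)
    return DiffusionFit(
        de=kappa_hat * radius**2,
        n_terms=n_terms,
        radius=radius,
        quality=goodness_of_fit(y, fitted),
        c_inf=c_inf,
        c0=c0,
        y_series=fitted,
        times_seconds=t,
        y_observed=y,
    )


def _refit_kappa_unbounded(
    kappa_start: float, t: np.ndarray, y_star: np.ndarray, n_terms: int
) -> float:
    """Fast unbounded Levenberg-Marquardt refit used inside the bootstrap."""
    result = least_squares(
        lambda p: _crank_y_kappa(p[0], t, n_terms) - y_star,
        x0=[kappa_start],
        jac=lambda p: _crank_dy_dkappa(p[0], t, n_terms)[:, np.newaxis],
        method="lm",
    )
    if not result.success:
        raise FitError(f"bootstrap refit failed: {result.message}")
    return float(result.x[0])


def bootstrap_de(
    fit: DiffusionFit,
    n_iterations: int = 2000,
    seed: int | None = None,
) -> BootstrapResult:
    """Residual-resampling bootstrap for the effective diffusivity.

    Algorithm: centre the fit residuals (eps' = eps - mean(eps)); for each of
    ``n_iterations`` draws, resample eps' with replacement, add to the fitted
    y values, refit kappa by an unbounded Levenberg-Marquardt started at the
    full-data estimate, truncate negative draws to 0 (the De >= 0 physical
    constraint), and record De* = kappa* R^2.  The standard error is the
    standard deviation of the draws; the confidence interval the 2.5/97.5
    percentiles (linear interpolation).

    Each iteration uses its own deterministic substream spawned from ``seed``,
    so results are reproducible and independent of execution order.  Refit
    failures are skipped and counted; more than 5 % failures is an error.
    """
    if fit.times_seconds is None or fit.y_observed is None:
        raise ValidationError("fit does not carry observed data; refit with fit_de")
    t = fit.times_seconds
    eps = fit.residuals
    eps_centered = eps - eps.mean()
    n = t.size
    r2 = fit.radius**2

    child_seeds = np.random.SeedSequence(seed).spawn(n_iterations)
    draws = np.empty(n_iterations)
    failures = 0
    kappa_hat = fit.kappa
    for b in range(n_iterations):
        rng = np.random.default_rng(child_seeds[b])
        idx = rng.integers(0, n, size=n)
        y_star = fit.y_series + eps_centered[idx]
        try:
            kappa_star = _refit_kappa_unbounded(kappa_hat, t, y_star, fit.n_terms)
        except (FitError, ValueError):
            draws[b] = np.nan
            failures += 1
            continue
        draws[b] = max(kappa_star, 0.0) * r2

    if failures > 0.05 * n_iterations:
        raise FitError(
            f"bootstrap unreliable: {failures}/{n_iterations} refits failed"
        )
    good = draws[~np.isnan(draws)]
    ci_low, ci_high = np.percentile(good, [2.5, 97.5])
    return BootstrapResult(
        point_estimate=fit.de,
        standard_error=float(good.std(ddof=1)) if good.size > 1 else 0.0,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_iterations=n_iterations,
        seed=seed,
        distribution=draws,
        n_failures=failures,
    )
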