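"""Shared domain types, delimited-text I/O and goodness-of-fit metrics.

Every downstream stage (pseudo-second-order kinetics, Fickian diffusion,
mass transfer, thermodynamics) consumes :class:`ExtractionCurve` objects
grouped into a :class:`StudyDataset` and reports fit quality through
:class:`FitQuality`.  Concentrations are in mg gallic-acid equivalents per
gram of dry plant material (mg GAE/g d.w.), times in minutes, temperatures
in degrees Celsius at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_PARTICLE_RADIUS",
    "ExtractionError",
    "ValidationError",
    "ConfigurationError",
    "ParseError",
    "DomainError",
    "FitError",
    "ExtractionCurve",
    "StudyDataset",
    "FitQuality",
    "celsius_to_kelvin",
    "goodness_of_fit",
    "relative_change",
    "read_curves",
    "write_curves",
    "to_json",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT: float = 8.314

#: Particle radius of the sieved leaf powder, metres (mean diameter 0.25 mm).
DEFAULT_PARTICLE_RADIUS: float = 1.25e-4

#: Canonical long-format column names.
CANONICAL_COLUMNS = ("time", "concentration", "temperature", "method", "replicate")


class ExtractionError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ExtractionError):
    """Input data violates a structural contract (shapes, ordering, duplicates)."""


class ConfigurationError(ExtractionError):
    """A required configuration item (e.g. a column mapping) is missing or wrong."""


class ParseError(ExtractionError):
    """A delimited-text cell could not be parsed; carries the offending row."""


class DomainError(ExtractionError):
    """A quantity is outside the mathematical domain of an operation."""


class FitError(ExtractionError):
    """A regression failed or produced physically inadmissible parameters."""


def celsius_to_kelvin(temperature_c: float | np.ndarray) -> float | np.ndarray:
    """Convert Celsius to Kelvin using the study convention K = degC + 273.

    The integer offset (rather than 273.15) is the convention under which the
    reported Gibbs-energy series is internally consistent with the reported
    enthalpy and entropy; it is applied uniformly wherever an absolute
    temperature enters a regression (Arrhenius, Van't Hoff, Gibbs).
    """
    kelvin = np.asarray(temperature_c, dtype=float) + 273.0
    return float(kelvin) if kelvin.ndim == 0 else kelvin


@dataclass(frozen=True)
class ExtractionCurve:
    """One extraction time course C_t(t) at fixed temperature/method/replicate.

    Parameters
    ----------
    times
        Sampling times in minutes; strictly increasing, all >= 0.
    concentrations
        Extracted-solute concentrations, mg GAE per g dry weight; finite, >= 0.
    temperature
        Bath temperature, degrees Celsius.
    method
        Extraction method label, e.g. ``"UAE"`` or ``"CSE"``.
    replicate
        Replicate identifier within the (temperature, method) cell.
    meta
        Free-form annotations (ethanol fraction, solvent-to-solid ratio, ...).
    """

    times: np.ndarray
    concentrations: np.ndarray
    temperature: float
    method: str = "UAE"
    replicate: str = "1"
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValidationError(
                f"times and concentrations must be 1-D of equal length "
                f"(got {t.shape} vs {c.shape})"
            )
        if t.size and (np.any(~np.isfinite(t)) or np.any(t < 0)):
            raise ValidationError("times must be finite and non-negative")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(~np.isfinite(c)) or np.any(c < 0):
            raise ValidationError("concentrations must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def key(self) -> tuple[float, str, str]:
        return (self.temperature, self.method, str(self.replicate))

    def to_dict(self) -> dict[str, Any]:
        return {
            "times": self.times.tolist(),
            "concentrations": self.concentrations.tolist(),
            "temperature": self.temperature,
            "method": self.method,
            "replicate": self.replicate,
            "meta": dict(self.meta),
        }


@dataclass
class StudyDataset:
    """A collection of extraction curves plus the shared physical constants."""

    curves: list[ExtractionCurve]
    particle_radius: float = DEFAULT_PARTICLE_RADIUS
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.particle_radius <= 0:
            raise ValidationError("particle_radius must be > 0")
        seen: set[tuple[float, str, str]] = set()
        for curve in self.curves:
            if curve.key in seen:
                raise ValidationError(
                    f"duplicate curve for (temperature, method, replicate)={curve.key}"
                )
            seen.add(curve.key)

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    def groups(self) -> dict[tuple[float, str], list[ExtractionCurve]]:
        """Curves grouped by (temperature, method), replicates together."""
        out: dict[tuple[float, str], list[ExtractionCurve]] = {}
        for curve in self.curves:
            out.setdefault((curve.temperature, curve.method), []).append(curve)
        return out

    def methods(self) -> list[str]:
        return sorted({c.method for c in self.curves})

    def temperatures(self, method: str | None = None) -> list[float]:
        return sorted(
            {c.temperature for c in self.curves if method is None or c.method == method}
        )


@dataclass(frozen=True)
class FitQuality:
    """Goodness-of-fit summary: R^2, mean square error and its root."""

    r_squared: float
    mse: float
    rmse: float
    n_points: int

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float]) -> FitQuality:
    """R^2 = 1 - SSres/SStot, MSE = SSres/n and RMSE = sqrt(MSE).

    R^2 is not clipped: a model worse than the mean of the observations
    yields a negative value.

    Raises
    ------
    ValidationError
        If the series lengths differ or fewer than two points are given.
    DomainError
        If the observations are all identical (zero total sum of squares,
        R^2 undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError(
            f"observed and predicted must be 1-D of equal length "
            f"(got {obs.shape} vs {pred.shape})"
        )
    n = obs.size
    if n < 2:
        raise ValidationError("goodness_of_fit needs at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("R^2 undefined: observed values are all identical")
    ss_res = float(np.sum((obs - pred) ** 2))
    mse = ss_res / n
    return FitQuality(
        r_squared=1.0 - ss_res / ss_tot,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        n_points=n,
    )


def relative_change(reference: float, value: float) -> float:
    """Signed percent change 100*(value - reference)/reference."""
    if reference == 0:
        raise DomainError("relative_change undefined for zero reference")
    return 100.0 * (value - reference) / reference


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _resolve_columns(
    columns: Iterable[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical column names to the file's actual column names."""
    dialect = dict(dialect or {})
    available = list(columns)
    resolved: dict[str, str] = {}
    for canonical in CANONICAL_COLUMNS:
        actual = dialect.get(canonical, canonical)
        if actual not in available:
            raise ConfigurationError(
                f"required column {canonical!r} (file column {actual!r}) "
                f"not found; file has {available}"
            )
        resolved[canonical] = actual
    return resolved


def read_curves(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> StudyDataset:
    """Read a long-format delimited file into a :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV (default) or TSV file with a header row; UTF-8.
    dialect
        Optional mapping from canonical column names
        (``time, concentration, temperature, method, replicate``) to the
        file's column names.
    sep
        Field separator; inferred (comma or tab) when omitted.

    One curve is produced per (temperature, method, replicate) group with
    its rows sorted by time; columns not consumed by the schema are
    preserved per-curve in ``meta`` (scalar if constant within the group).
    """
    path = Path(path)
    if sep is None:
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    cols = _resolve_columns(frame.columns, dialect)

    for canonical in ("time", "concentration", "temperature"):
        actual = cols[canonical]
        numeric = pd.to_numeric(frame[actual], errors="coerce")
        bad = numeric.isna() & frame[actual].notna()
        if frame[actual].isna().any():
            bad |= frame[actual].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"non-numeric value {frame[actual][bad.idxmax()]!r} in column "
                f"{actual!r} at file row {row}"
            )
        frame[actual] = numeric

    extra_cols = [c for c in frame.columns if c not in cols.values()]
    curves: list[ExtractionCurve] = []
    grouped = frame.groupby(
        [cols["temperature"], cols["method"], cols["replicate"]], sort=True
    )
    for (temperature, method, replicate), grp in grouped:
        times = grp[cols["time"]].to_numpy(dtype=float)
        if np.unique(times).size != times.size:
            raise ValidationError(
                f"duplicate time points within curve "
                f"(temperature={temperature}, method={method}, replicate={replicate})"
            )
        order = np.argsort(times)
        meta: dict[str, Any] = {}
        for col in extra_cols:
            values = grp[col].to_numpy()
            uniq = pd.unique(grp[col])
            meta[col] = uniq[0] if len(uniq) == 1 else list(values[order])
        curves.append(
            ExtractionCurve(
                times=times[order],
                concentrations=grp[cols["concentration"]].to_numpy(dtype=float)[order],
                temperature=float(temperature),
                method=str(method),
                replicate=str(replicate),
                meta=meta,
            )
        )
    return StudyDataset(curves=curves)


def write_curves(
    dataset: StudyDataset, path: str | Path, sep: str = ","
) -> None:
    """Write a dataset in the same long-format schema ``read_curves`` reads.

    Scalar ``meta`` entries become extra columns; floats are written at full
    repr precision so a read/write round-trip is lossless to ~1e-16.
    """
    rows: list[dict[str, Any]] = []
    for curve in dataset:
        scalar_meta = {
            k: v for k, v in curve.meta.items() if not isinstance(v, (list, np.ndarray))
        }
        for t, c in zip(curve.times, curve.concentrations):
            rows.append(
                {
                    "time": repr(float(t)),
                    "concentration": repr(float(c)),
                    "temperature": repr(float(curve.temperature)),
                    "method": curve.method,
                    "replicate": curve.replicate,
                    **scalar_meta,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def to_json(obj: Any, **kwargs: Any) -> str:
    """Serialize any result object (dataclass / mapping / array) to JSON."""
    return json.dumps(_jsonable(obj), **kwargs)


def warn(message: str) -> None:
    """Emit a package-level warning (single funnel so tests can assert)."""
    warnings.warn(message, UserWarning, stacklevel=3)
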