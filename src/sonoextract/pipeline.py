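"""End-to-end orchestration of the inference chain.

For every (temperature, method) cell of a :class:`StudyDataset`:
pseudo-second-order fit per replicate (mean +/- SD across replicates) ->
unaccomplished-ratio transform with C_inf = fitted C_s -> Crank De fit at
each requested series truncation with a residual bootstrap -> external
mass-transfer coefficient and Biot number; then, across temperatures per
method: Arrhenius activation energy and the Van't Hoff/Gibbs thermodynamic
series.  Results are assembled into pandas tables mirroring the standard
reporting layout (kinetics / diffusion / transport-thermodynamics /
method-comparison) with full provenance.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    DEFAULT_PARTICLE_RADIUS,
    ExtractionCurve,
    FitError,
    StudyDataset,
    ValidationError,
    relative_change,
)
from .fickian_diffusion import bootstrap_de, fit_de, unaccomplished_ratio
from .mass_transfer import transport_analysis
from .pso_kinetics import fit_arrhenius, fit_pso_linearized
from .thermodynamics import thermo_analysis

__all__ = ["StudyConfig", "ReportBundle", "run_study", "compare_methods"]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full study run (defaults follow the study settings)."""

    n_terms: tuple[int, ...] = (1, 10, 20)
    bootstrap_iterations: int = 2000
    seed: int = 0
    c_max: float = 175.0
    characteristic_length: float | None = None  # default R/3
    biot_length: float | None = None  # default 2R
    biot_n_terms: int = 10  # truncation whose De feeds the Biot number
    arrhenius_temperatures: tuple[float, ...] | None = None  # default: all
    refine_nonlinear: bool = False
    c_inf_source: str = "pso"  # "pso" (fitted C_s) or "final" (last measured C_t)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """All study outputs: four tables, raw result objects, and provenance."""

    kinetics_table: pd.DataFrame
    diffusion_table: pd.DataFrame
    transport_thermo_table: pd.DataFrame
    comparison_table: pd.DataFrame | None
    results: dict[str, Any] = field(default_factory=dict, repr=False)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, **kwargs: Any) -> str:
        payload = {
            "kinetics_table": self.kinetics_table.to_dict(orient="records"),
            "diffusion_table": self.diffusion_table.to_dict(orient="records"),
            "transport_thermo_table": self.transport_thermo_table.to_dict(
                orient="records"
            ),
            "comparison_table": (
                self.comparison_table.to_dict(orient="records")
                if self.comparison_table is not None
                else None
            ),
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True, **kwargs)


def _mean_curve(curves: list[ExtractionCurve]) -> ExtractionCurve:
    """Average replicate concentrations on a shared time grid."""
    base = curves[0]
    for other in curves[1:]:
        if not np.array_equal(other.times, base.times):
            raise ValidationError(
                "replicates must share a common time grid for curve averaging"
            )
    mean_conc = np.mean([c.concentrations for c in curves], axis=0)
    return ExtractionCurve(
        times=base.times,
        concentrations=mean_conc,
        temperature=base.temperature,
        method=base.method,
        replicate="mean",
        meta=dict(base.meta),
    )


def run_study(dataset: StudyDataset, config: StudyConfig | None = None) -> ReportBundle:
    """Run the full kinetic/diffusion/transport/thermodynamic chain.

    Failures in one (temperature, method) group are recorded in the
    provenance log and do not abort the other groups; an empty successful
    set raises :class:`FitError`.  Given the same dataset, config and seed,
    the serialized bundle is byte-identical across runs.
    """
    config = config or StudyConfig()
    radius = dataset.particle_radius
    l_c = config.characteristic_length or radius / 3.0
    biot_length = config.biot_length or 2.0 * radius

    log: list[str] = []
    errors: dict[str, str] = {}
    kin_rows: list[dict[str, Any]] = []
    diff_rows: list[dict[str, Any]] = []
    trans_rows: list[dict[str, Any]] = []
    results: dict[str, Any] = {"pso": {}, "diffusion": {}, "transport": {}}

    groups = dict(sorted(dataset.groups().items(), key=lambda kv: (kv[0][1], kv[0][0])))
    seed_seq = np.random.SeedSequence(config.seed)
    group_seeds = {
        key: int(child.generate_state(1)[0] % (2**31))
        for key, child in zip(groups, seed_seq.spawn(len(groups)))
    }

    for (temperature, method), curves in groups.items():
        label = f"{method}@{temperature:g}C"
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                replicate_fits = [
                    fit_pso_linearized(c, refine=config.refine_nonlinear)
                    for c in curves
                ]
                cs_values = np.array([f.cs for f in replicate_fits])
                k_values = np.array([f.k for f in replicate_fits])
                mean_curve = _mean_curve(curves)
                pooled = fit_pso_linearized(mean_curve, method_label=method)
                cs_hat = float(cs_values.mean())
                k_hat = float(k_values.mean())

                c_inf = (
                    cs_hat
                    if config.c_inf_source == "pso"
                    else float(mean_curve.concentrations[-1])
                )
                y_series = unaccomplished_ratio(mean_curve, c_inf=c_inf)

                de_fits = {}
                boots = {}
                for n_terms in config.n_terms:
                    fit = fit_de(y_series, radius=radius, n_terms=n_terms, c_inf=c_inf)
                    boot = bootstrap_de(
                        fit,
                        n_iterations=config.bootstrap_iterations,
                        seed=group_seeds[(temperature, method)] + n_terms,
                    )
                    de_fits[n_terms] = fit
                    boots[n_terms] = boot
                    diff_rows.append(
                        {
                            "temperature": temperature,
                            "method": method,
                            "n_terms": n_terms,
                            "de": fit.de,
                            "de_se": boot.standard_error,
                            "ci_low": boot.ci_low,
                            "ci_high": boot.ci_high,
                            "r_squared": fit.quality.r_squared,
                        }
                    )

                de_for_biot = de_fits[config.biot_n_terms].de
                transport = transport_analysis(
                    mean_curve,
                    cs=cs_hat,
                    de=de_for_biot,
                    characteristic_length=l_c,
                    biot_length=biot_length,
                )
            for w in caught:
                log.append(f"{label}: {w.message}")
        except (FitError, ValidationError) as exc:
            errors[label] = str(exc)
            log.append(f"{label}: FAILED: {exc}")
            continue

        kin_rows.append(
            {
                "temperature": temperature,
                "method": method,
                "cs": cs_hat,
                "cs_sd": float(cs_values.std(ddof=1)) if len(curves) > 1 else 0.0,
                "k": k_hat,
                "k_sd": float(k_values.std(ddof=1)) if len(curves) > 1 else 0.0,
                "h": k_hat * cs_hat**2,
                "r_squared": pooled.quality.r_squared,
                "mse": pooled.quality.mse,
                "rmse": pooled.quality.rmse,
            }
        )
        trans_rows.append(
            {
                "temperature": temperature,
                "method": method,
                "de": de_for_biot,
                "kt": transport.kt,
                "biot": transport.biot,
                "rate_limit": (
                    "internal-diffusion-limited"
                    if transport.biot > 50
                    else "external-transfer-limited"
                ),
            }
        )
        results["pso"][label] = replicate_fits
        results["diffusion"][label] = {"fits": de_fits, "bootstraps": boots}
        results["transport"][label] = transport

    if not kin_rows:
        raise FitError(f"all groups failed: {errors}")

    kinetics = pd.DataFrame(kin_rows).sort_values(["method", "temperature"])
    diffusion = pd.DataFrame(diff_rows).sort_values(["method", "temperature", "n_terms"])
    transport_df = pd.DataFrame(trans_rows).sort_values(["method", "temperature"])

    # Across-temperature stages, per method.
    results["arrhenius"] = {}
    results["thermo"] = {}
    thermo_cols = []
    for method in kinetics["method"].unique():
        sub = kinetics[kinetics["method"] == method]
        arr_sub = sub
        if config.arrhenius_temperatures is not None:
            arr_sub = sub[sub["temperature"].isin(config.arrhenius_temperatures)]
        if len(arr_sub) >= 2:
            results["arrhenius"][method] = fit_arrhenius(
                list(zip(arr_sub["temperature"], arr_sub["k"])),
                gas_constant=dataset.gas_constant,
            )
        if len(sub) >= 2:
            thermo = thermo_analysis(
                list(zip(sub["temperature"], sub["cs"])),
                c_max=config.c_max,
                gas_constant=dataset.gas_constant,
            )
            results["thermo"][method] = thermo
            gibbs = {t_k: g for t_k, g in thermo.delta_g_series}
            thermo_cols.append(
                pd.DataFrame(
                    {
                        "temperature": sub["temperature"],
                        "method": method,
                        "delta_h": thermo.delta_h,
                        "delta_s": thermo.delta_s,
                        "delta_g": [
                            gibbs[t_c + 273.0] for t_c in sub["temperature"]
                        ],
                    }
                )
            )
    if thermo_cols:
        transport_df = transport_df.merge(
            pd.concat(thermo_cols), on=["temperature", "method"], how="left"
        )

    bundle = ReportBundle(
        kinetics_table=kinetics.reset_index(drop=True),
        diffusion_table=diffusion.reset_index(drop=True),
        transport_thermo_table=transport_df.reset_index(drop=True),
        comparison_table=None,
        results=results,
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "particle_radius": radius,
            "characteristic_length": l_c,
            "biot_length": biot_length,
            "version": __version__,
            "log": log,
            "errors": errors,
        },
    )
    if len(kinetics["method"].unique()) >= 2:
        bundle.comparison_table = compare_methods(bundle)
    return bundle


def compare_methods(
    bundle: ReportBundle, reference: str = "CSE", other: str = "UAE"
) -> pd.DataFrame:
    """Side-by-side method comparison with signed percent differences.

    Values are compared at each method's optimum temperature (maximum cs);
    the percent difference is relative to the ``reference`` method
    (conventional extraction by default).
    """
    kin = bundle.kinetics_table
    present = set(kin["method"])
    if not {reference, other} <= present:
        raise ValidationError(
            f"comparison needs methods {reference!r} and {other!r}; have {sorted(present)}"
        )

    def best_row(frame: pd.DataFrame, method: str) -> pd.Series:
        sub = frame[frame["method"] == method]
        return sub.loc[sub["cs"].idxmax()]

    rows = []
    trans = bundle.transport_thermo_table
    for parameter in ("cs", "k", "de", "kt"):
        values = {}
        for method in (other, reference):
            kin_row = best_row(kin, method)
            if parameter in kin.columns:
                values[method] = float(kin_row[parameter])
            else:
                t_row = trans[
                    (trans["method"] == method)
                    & (trans["temperature"] == kin_row["temperature"])
                ].iloc[0]
                values[method] = float(t_row[parameter])
        rows.append(
            {
                "parameter": parameter,
                other: values[other],
                reference: values[reference],
                "percent_difference": relative_change(
                    values[reference], values[other]
                ),
            }
        )
    return pd.DataFrame(rows)
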