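"""Orchestration of the off-line and on-line flux-analysis paths.

Both paths share one implementation: a steady-state window is detected for
each scheduled dilution rate, specific extracellular rates with propagated
uncertainties are computed from the window, and the rates are balanced
against the stoichiometric network with a consistency test.  The paths
differ only in where the biomass and glycerol concentrations come from --
off-line assay records, or PLS predictions from in-situ spectra at 30-min
cadence -- so agreement between them demonstrates that the spectroscopic
soft sensor can replace the wet-chemistry assays as the input to flux
analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mfa import FluxEstimate, MeasuredFluxSet, estimate_fluxes, flux_report
from .network import StoichiometricModel, load_network, load_pichia_network
from .nirs import PLSCalibration, SpectraSet, calibrate, sel
from .rates import (
    ChemostatTimeSeries,
    ExtracellularRates,
    SteadyStateWindow,
    build_measured_flux_set,
    compare_rate_sets,
    detect_steady_state,
    estimate_state_rates,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StateResult",
    "run_state",
    "run_offline_path",
    "run_online_path",
    "online_series_from_predictions",
    "make_report",
    "render_markdown",
]

#: Default analyte windows (nm) and latent-variable counts.
DEFAULT_WINDOWS = {"biomass": (1250.0, 1350.0), "glycerol": (1500.0, 1800.0)}
DEFAULT_LVS = {"biomass": 5, "glycerol": 3}


@dataclass
class PipelineConfig:
    network_path: str | None = None        # None -> packaged P. pastoris net
    series_path: str | None = None
    spectra_path: str | None = None
    out_dir: str = "rtmfa_out"
    states: tuple[tuple[str, float], ...] = (("A", 0.05), ("B", 0.10), ("C", 0.15))
    S_in: float = 40.0
    window_size: int = 6
    alpha: float = 0.05
    n_val: int = 30
    seed: int = 7
    lvs: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LVS))
    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )


@dataclass
class StateResult:
    label: str
    window: SteadyStateWindow
    rates: ExtracellularRates
    measured: MeasuredFluxSet
    estimate: FluxEstimate

    @property
    def consistency(self):
        return self.estimate.consistency


def run_state(
    network: StoichiometricModel,
    series: ChemostatTimeSeries,
    label: str,
    D: float,
    S_in: float,
    window_size: int = 6,
    alpha: float = 0.05,
    tolerances=None,
) -> StateResult:
    """Window -> rates -> metabolite balancing for one steady state.

    This single function is the shared backbone of the off-line and on-line
    paths.
    """
    window = detect_steady_state(series, D, n_points=window_size, label=label,
                                 tolerances=tolerances)
    if window is None:
        raise RuntimeError(f"no steady state: {label}")
    rates = estimate_state_rates(series, window, S_in)
    measured = build_measured_flux_set(rates, network)
    estimate = estimate_fluxes(network, measured, alpha=alpha)
    cons = estimate.consistency
    logger.info(
        "state %s: D=%.3f mu=%.4f q_gly=%.3f q_o2=%.3f q_co2=%.3f "
        "h=%.3f df=%d verdict=%s",
        label, window.D, rates.mu, rates.q_gly, rates.q_o2, rates.q_co2,
        cons.h, cons.df, cons.verdict,
    )
    return StateResult(label=label, window=window, rates=rates,
                       measured=measured, estimate=estimate)


def run_offline_path(
    network: StoichiometricModel,
    series: ChemostatTimeSeries,
    states: Sequence[tuple[str, float]],
    S_in: float,
    window_size: int = 6,
    alpha: float = 0.05,
) -> dict[str, StateResult]:
    """Off-line assays -> rates -> MFA, per scheduled steady state."""
    return {
        label: run_state(network, series, label, D, S_in, window_size, alpha)
        for label, D in states
    }


def online_series_from_predictions(
    spectra: SpectraSet,
    calibrations: Mapping[str, PLSCalibration],
    gas_series: ChemostatTimeSeries,
) -> ChemostatTimeSeries:
    """Assemble a 30-min-cadence series from PLS concentration predictions.

    Biomass and glycerol come from the spectra; feed, volume and the gas
    channels (measured by the off-gas analyzer, not the spectrometer) are
    interpolated from the process record onto the spectral timestamps.  The
    per-channel sds of the predicted analytes are the models' RMSEP.
    """
    X_pred = np.clip(calibrations["biomass"].predict(spectra), 0.0, None)
    S_pred = np.clip(calibrations["glycerol"].predict(spectra), 0.0, None)
    t = spectra.times
    lo, hi = gas_series.time[0], gas_series.time[-1]
    keep = (t >= lo) & (t <= hi)
    t = t[keep]
    interp = lambda y: np.interp(t, gas_series.time, y)
    sd = {
        "X": _rmsep_or(calibrations["biomass"], gas_series.sd.get("X", 0.0)),
        "S": _rmsep_or(calibrations["glycerol"], gas_series.sd.get("S", 0.0)),
        "OUR": gas_series.sd.get("OUR", 0.0),
        "CER": gas_series.sd.get("CER", 0.0),
    }
    return ChemostatTimeSeries(
        t, interp(gas_series.F), interp(gas_series.V),
        X_pred[keep], S_pred[keep], interp(gas_series.OUR), interp(gas_series.CER),
        sd,
    )


def _rmsep_or(model: PLSCalibration, fallback: float) -> float:
    if model.report is not None and model.report.rmsep is not None:
        return float(model.report.rmsep)
    return fallback


def run_online_path(
    network: StoichiometricModel,
    spectra: SpectraSet,
    calibrations: Mapping[str, PLSCalibration],
    gas_series: ChemostatTimeSeries,
    states: Sequence[tuple[str, float]],
    S_in: float,
    window_size: int = 6,
    alpha: float = 0.05,
) -> dict[str, StateResult]:
    """Spectra -> PLS predictions -> rates -> MFA, per steady state.

    Calls the identical ``run_state`` backbone as the off-line path."""
    for name in ("biomass", "glycerol"):
        if name not in calibrations:
            raise KeyError(f"missing calibration for {name!r}")
    online = online_series_from_predictions(spectra, calibrations, gas_series)
    return {
        label: run_state(network, online, label, D, S_in, window_size, alpha)
        for label, D in states
    }


# -- reporting ----------------------------------------------------------------


def make_report(
    offline: Mapping[str, StateResult],
    online: Mapping[str, StateResult] | None = None,
    calibrations: Mapping[str, PLSCalibration] | None = None,
    glycerol_flux_id: str = "r40",
) -> dict:
    """Consistency, state-summary, calibration and flux tables as a dict.

    The consistency table mirrors the study layout: per state the test df,
    the index from experimental (off-line) rates, the index from NIR
    (on-line) rates, the chi-square critical value and the verdict.
    """
    report: dict = {"consistency": [], "states": [], "fluxes": {}}
    for label, res in offline.items():
        cons = res.consistency
        row = {
            "state": label,
            "df": cons.df,
            "h_exp": round(cons.h, 2),
            "h_nir": None,
            "chi2": round(cons.chi2_critical, 2),
            "verdict": cons.verdict,
        }
        if online and label in online:
            oc = online[label].consistency
            row["h_nir"] = round(oc.h, 2)
            if oc.verdict == "fail":
                row["verdict"] = "fail"
        report["consistency"].append(row)
        r = res.rates
        report["states"].append({
            "state": label,
            "D": round(r.D, 3),
            "CER_mmol_L_h": round(r.q_co2 * r.x_bar, 2),
            "OUR_mmol_L_h": round(r.q_o2 * r.x_bar, 2),
            "RQ": round(r.rq, 2),
            "yield_gdcw_per_g": round(r.yield_xs, 2),
        })
        table = flux_report(res.estimate, glycerol_flux_id=glycerol_flux_id)
        fluxes = {
            "offline": {
                rid: round(val, 4)
                for rid, val in zip(table["reaction"], table["flux"])
            }
        }
        if online and label in online:
            t2 = flux_report(online[label].estimate, glycerol_flux_id=glycerol_flux_id)
            fluxes["online"] = {
                rid: round(val, 4)
                for rid, val in zip(t2["reaction"], t2["flux"])
            }
        report["fluxes"][label] = fluxes
    if calibrations:
        report["calibration"] = {
            name: model.report.rounded() if model.report else None
            for name, model in calibrations.items()
        }
    return report


def render_markdown(report: dict) -> str:
    lines = ["# Flux analysis report", "", "## Consistency test", ""]
    lines.append("| State | DF | h (off-line) | h (NIR) | chi2 | Verdict |")
    lines.append("|---|---|---|---|---|---|")
    for row in report["consistency"]:
        h_nir = "-" if row["h_nir"] is None else f"{row['h_nir']:.2f}"
        lines.append(
            f"| {row['state']} | {row['df']} | {row['h_exp']:.2f} | {h_nir} "
            f"| {row['chi2']:.2f} | {row['verdict']} |"
        )
    lines += ["", "## Steady states", ""]
    lines.append("| State | D (1/h) | CER | OUR | RQ | Yield |")
    lines.append("|---|---|---|---|---|---|")
    for row in report["states"]:
        lines.append(
            f"| {row['state']} | {row['D']:.3f} | {row['CER_mmol_L_h']} "
            f"| {row['OUR_mmol_L_h']} | {row['RQ']:.2f} "
            f"| {row['yield_gdcw_per_g']} |"
        )
    if "calibration" in report:
        lines += ["", "## Calibration models", ""]
        lines.append("| Analyte | LV | RMSEC | R2 | RMSECV | R2cv | RMSEP | R2ext | RMSEP/RMSECV |")
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for name, rep in report["calibration"].items():
            if rep is None:
                continue
            lines.append(
                f"| {name} | | {rep['rmsec']} | {rep['r2_cal']} | {rep['rmsecv']} "
                f"| {rep['r2_cv']} | {rep['rmsep']} | {rep['r2_ext']} "
                f"| {rep['rmsep_rmsecv_ratio']} |"
            )
    return "\n".join(lines) + "\n"


def write_outputs(
    out_dir: str | Path,
    offline: Mapping[str, StateResult],
    online: Mapping[str, StateResult] | None,
    report: dict,
) -> None:
    """One directory per run: rates_{state}.json, fluxes_{state}.json,
    report.json and report.md, all deterministic for fixed seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, res in offline.items():
        rates_doc = {
            "label": label,
            "D": res.rates.D,
            "rates": dict(zip(res.rates.names, res.rates.values.tolist())),
            "sd": dict(zip(res.rates.names, res.rates.sd.tolist())),
            "RQ": res.rates.rq,
            "yield": res.rates.yield_xs,
            "n_points": res.rates.n_points,
        }
        (out / f"rates_{label}.json").write_text(
            json.dumps(rates_doc, sort_keys=True, indent=1)
        )
        flux_doc = {
            "unknown": dict(zip(res.estimate.unknown_ids, res.estimate.r_n.tolist())),
            "measured_adjusted": dict(
                zip(res.estimate.measured_ids, res.estimate.r_b_adjusted.tolist())
            ),
            "sd_unknown": dict(zip(res.estimate.unknown_ids, res.estimate.sd_n.tolist())),
            "consistency": {
                "h": res.consistency.h,
                "df": res.consistency.df,
                "chi2_critical": res.consistency.chi2_critical,
                "verdict": res.consistency.verdict,
            },
        }
        (out / f"fluxes_{label}.json").write_text(
            json.dumps(flux_doc, sort_keys=True, indent=1)
        )
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    (out / "report.md").write_text(render_markdown(report))
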