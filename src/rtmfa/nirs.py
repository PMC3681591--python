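"""Chemometric calibration: spectral preprocessing, PLS regression and
method qualification.

The soft-sensor chain is: Savitzky-Golay second-derivative filtering (which
removes baseline offset and slope), exclusion of the saturated water bands
and the noisy long-wavelength region, selection of an analyte-specific
wavelength window, mean-centering, and PLS1 regression against off-line
reference values interpolated to the spectral timestamps.  Model quality is
judged by RMSEC/RMSECV/RMSEP and R-squared, and qualified against the
standard error of the laboratory (SEL) of the reference assay: a model with
RMSEP below 1.5 x SEL quantifies as precisely as the reference method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "SpectraSet",
    "PreprocessConfig",
    "PLSCalibration",
    "ValidationReport",
    "SELResult",
    "read_spectra",
    "write_spectra",
    "preprocess",
    "select_window",
    "interpolate_reference",
    "split_calibration_validation",
    "fit_pls",
    "cross_validate",
    "validate_external",
    "calibrate",
    "sel",
    "qualify_model",
    "save_calibration",
    "load_calibration",
]


@dataclass
class SpectraSet:
    """Absorbance spectra on a common wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray  # (n_spectra, n_channels)
    times: np.ndarray       # hours

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape != (len(self.times), len(self.wavelengths)):
            raise ValueError("absorbance must be (n_spectra, n_channels)")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains missing values")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("timestamps must be nondecreasing")

    def subset(self, rows: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.wavelengths, self.absorbance[rows], self.times[rows])


@dataclass(frozen=True)
class PreprocessConfig:
    """Savitzky-Golay derivative + band exclusion + mean-centering settings.

    The default excluded bands blank the dominant water absorptions
    (1400 and 1900 nm, +/- 20 nm) and everything above 2000 nm, where
    silica-fibre probes are noisy.
    """

    sg_window: int = 33
    sg_polyorder: int = 2
    sg_derivative: int = 2
    mean_center: bool = True
    excluded_bands: tuple[tuple[float, float], ...] = (
        (1380.0, 1420.0), (1880.0, 1920.0), (2000.0, float("inf")),
    )

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("SG window must be odd and larger than the polyorder")
        if self.sg_derivative > self.sg_polyorder:
            raise ValueError("SG derivative order cannot exceed the polyorder")


def preprocess(
    spectra: SpectraSet,
    config: PreprocessConfig = PreprocessConfig(),
    training_means: np.ndarray | None = None,
) -> SpectraSet:
    """Derivative-filter and (optionally) mean-center a spectra set.

    The excluded bands are removed first and the SG filter runs separately
    over each remaining contiguous wavelength segment, so the derivative
    never bridges a gap.  ``training_means`` (from a calibration set) are
    subtracted when given; otherwise the set's own column means are used.
    A segment shorter than the filter window is an error naming the segment.
    """
    keep = np.ones(len(spectra.wavelengths), dtype=bool)
    for lo, hi in config.excluded_bands:
        keep &= ~((spectra.wavelengths >= lo) & (spectra.wavelengths <= hi))
    wl = spectra.wavelengths[keep]
    if wl.size == 0:
        raise ValueError("band exclusion removed every channel")
    X = spectra.absorbance[:, keep]
    delta = float(np.median(np.diff(wl))) if len(wl) > 1 else 1.0
    out = np.empty_like(X)
    for start, stop in _segments_from_grid(wl, delta):
        if stop - start < config.sg_window:
            raise ValueError(
                f"segment {wl[start]:.0f}-{wl[stop - 1]:.0f} nm has "
                f"{stop - start} channels, shorter than the SG window "
                f"({config.sg_window})"
            )
        out[:, start:stop] = savgol_filter(
            X[:, start:stop], window_length=config.sg_window,
            polyorder=config.sg_polyorder, deriv=config.sg_derivative,
            delta=delta, axis=1,
        )
    if config.mean_center:
        means = training_means if training_means is not None else out.mean(axis=0)
        out = out - means
    return SpectraSet(wl, out, spectra.times)


def _segments_from_grid(wl: np.ndarray, delta: float) -> list[tuple[int, int]]:
    """Split a (possibly gapped) retained grid into contiguous segments."""
    if len(wl) < 2:
        return [(0, len(wl))]
    gaps = np.where(np.diff(wl) > 1.5 * delta)[0]
    bounds = [0] + [int(g) + 1 for g in gaps] + [len(wl)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def select_window(spectra: SpectraSet, interval: tuple[float, float]) -> SpectraSet:
    """Retain channels within ``[lo, hi]`` inclusive, order preserved."""
    lo, hi = interval
    mask = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if not np.any(mask):
        raise ValueError(f"window {lo}-{hi} nm selects no channels")
    return SpectraSet(spectra.wavelengths[mask], spectra.absorbance[:, mask],
                      spectra.times)


def interpolate_reference(
    ref_times: np.ndarray,
    ref_values: np.ndarray,
    query_times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation of off-line references to query times.

    Queries outside the reference range are dropped with a warning (no
    extrapolation).  Returns ``(values, kept_mask)`` aligned to the kept
    queries.
    """
    ref_times = np.asarray(ref_times, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    query_times = np.asarray(query_times, dtype=float)
    if len(ref_times) < 2:
        raise ValueError("need at least 2 reference points")
    if not np.all(np.diff(ref_times) > 0):
        raise ValueError("reference times must be sorted and unique")
    inside = (query_times >= ref_times[0]) & (query_times <= ref_times[-1])
    if not np.all(inside):
        warnings.warn(
            f"{int((~inside).sum())} query times outside the reference range "
            "were dropped (no extrapolation)"
        )
    return np.interp(query_times[inside], ref_times, ref_values), inside


def split_calibration_validation(
    n: int, n_val: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random, disjoint, exhaustive calibration/validation index split."""
    if not 0 < n_val < n:
        raise ValueError("need 0 < n_val < n")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


# -- PLS ----------------------------------------------------------------------


@dataclass
class ValidationReport:
    analyte: str
    rmsec: float
    r2_cal: float
    rmsecv: float | None = None
    r2_cv: float | None = None
    rmsep: float | None = None
    r2_ext: float | None = None
    n_cal: int = 0
    n_val: int = 0

    @property
    def rmsep_rmsecv_ratio(self) -> float | None:
        if self.rmsep is None or not self.rmsecv:
            return None
        return round(self.rmsep, 2) / round(self.rmsecv, 2)

    def rounded(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, 2) if isinstance(v, float) else v
        ratio = self.rmsep_rmsecv_ratio
        out["rmsep_rmsecv_ratio"] = None if ratio is None else round(ratio, 2)
        return out


@dataclass
class PLSCalibration:
    """A fitted PLS1 model plus everything needed to apply it to new spectra."""

    analyte: str
    window: tuple[float, float]
    n_lv: int
    preprocess_config: PreprocessConfig
    training_means: np.ndarray      # derivative-space means, full retained grid
    wavelengths: np.ndarray         # retained grid (post-exclusion)
    coef: np.ndarray                # regression vector on the window channels
    x_mean: np.ndarray
    y_mean: float
    report: ValidationReport | None = None

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        deriv = preprocess(spectra, self.preprocess_config,
                           training_means=self.training_means)
        if len(deriv.wavelengths) != len(self.wavelengths) or not np.allclose(
            deriv.wavelengths, self.wavelengths
        ):
            raise ValueError("spectra wavelength grid does not match the model")
        sub = select_window(deriv, self.window)
        return (sub.absorbance - self.x_mean) @ self.coef + self.y_mean


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> tuple[np.ndarray, np.ndarray, float]:
    """PLS1 regression vector from (preprocessed) spectra.

    Returns ``(coef, x_mean, y_mean)`` such that predictions are
    ``(X - x_mean) @ coef + y_mean``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}] for this data")
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(X, y)
    return pls.coef_.reshape(-1), X.mean(axis=0), float(y.mean())


def cross_validate(
    X: np.ndarray, y: np.ndarray, n_lv: int, scheme: str | tuple[str, int] = "loo"
) -> tuple[float, float]:
    """RMSECV and cross-validated R-squared.

    ``scheme`` is ``"loo"`` (default, small data sets) or ``("blocks", k)``
    for k contiguous blocks, which respects serial correlation in process
    data.  Centering statistics are recomputed inside each training fold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2:
        raise ValueError("cross-validation needs at least 2 samples")
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif isinstance(scheme, tuple) and scheme[0] == "blocks":
        folds = [f for f in np.array_split(np.arange(n), scheme[1]) if len(f)]
    else:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")
    yhat = np.empty(n)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        if len(train) < 1:
            raise ValueError("a fold left no training samples")
        coef, x_mean, y_mean = fit_pls(X[train], y[train], n_lv)
        yhat[test] = (X[test] - x_mean) @ coef + y_mean
    return _rmse(y, yhat), _r2(y, yhat)


def validate_external(
    calibration: PLSCalibration, X_val: np.ndarray, y_val: np.ndarray
) -> ValidationReport:
    """External validation on a held-out set; fills RMSEP, external R2 and
    the RMSEP/RMSECV ratio of the calibration's report."""
    y_val = np.asarray(y_val, dtype=float).ravel()
    if len(y_val) == 0:
        raise ValueError("validation set is empty")
    yhat = (np.atleast_2d(X_val) - calibration.x_mean) @ calibration.coef \
        + calibration.y_mean
    report = calibration.report
    if report is None:
        report = ValidationReport(analyte=calibration.analyte, rmsec=float("nan"),
                                  r2_cal=float("nan"))
    report.rmsep = _rmse(y_val, yhat)
    report.r2_ext = _r2(y_val, yhat)
    report.n_val = len(y_val)
    calibration.report = report
    return report


def calibrate(
    spectra: SpectraSet,
    ref_times: np.ndarray,
    ref_values: np.ndarray,
    analyte: str,
    window: tuple[float, float],
    n_lv: int,
    n_val: int = 30,
    seed: int = 7,
    config: PreprocessConfig = PreprocessConfig(),
    cv_scheme: str | tuple[str, int] = "loo",
) -> PLSCalibration:
    """End-to-end calibration of one analyte from raw spectra + references.

    Interpolates the off-line reference values to the spectral timestamps,
    derivative-filters the spectra, selects the analyte window, splits
    calibration/validation samples at random, fits the PLS model, and fills
    a full validation report (RMSEC, RMSECV, RMSEP, R-squared values).
    """
    y_all, kept = interpolate_reference(ref_times, ref_values, spectra.times)
    usable = spectra.subset(np.where(kept)[0])
    # derivative without centering, so the stored means live in derivative
    # space over the full retained grid (applied to new spectra at predict)
    raw_cfg = PreprocessConfig(
        sg_window=config.sg_window, sg_polyorder=config.sg_polyorder,
        sg_derivative=config.sg_derivative, mean_center=False,
        excluded_bands=config.excluded_bands,
    )
    deriv_raw = preprocess(usable, raw_cfg)
    cal_idx, val_idx = split_calibration_validation(len(y_all), n_val, seed)
    training_means = deriv_raw.absorbance[cal_idx].mean(axis=0)

    sub = select_window(deriv_raw, window)
    X_cal, y_cal = sub.absorbance[cal_idx], y_all[cal_idx]
    X_val, y_val = sub.absorbance[val_idx], y_all[val_idx]

    coef, x_mean, y_mean = fit_pls(X_cal, y_cal, n_lv)
    yhat_cal = (X_cal - x_mean) @ coef + y_mean
    report = ValidationReport(
        analyte=analyte, rmsec=_rmse(y_cal, yhat_cal), r2_cal=_r2(y_cal, yhat_cal),
        n_cal=len(y_cal),
    )
    report.rmsecv, report.r2_cv = cross_validate(X_cal, y_cal, n_lv, cv_scheme)
    model = PLSCalibration(
        analyte=analyte, window=tuple(window), n_lv=n_lv,
        preprocess_config=raw_cfg, training_means=training_means,
        wavelengths=deriv_raw.wavelengths, coef=coef, x_mean=x_mean,
        y_mean=y_mean, report=report,
    )
    validate_external(model, X_val, y_val)
    return model


# -- reference method qualification -------------------------------------------


@dataclass(frozen=True)
class SELResult:
    """Standard error of the laboratory: pooled within-replicate sd."""

    sel: float
    sd_mean: float
    n_samples: int
    n_replicates: int


def sel(replicate_table: np.ndarray) -> SELResult:
    """SEL from an (N samples x r replicates) table of reference assays.

    ``SEL = sqrt( sum_j sum_i (y_ij - ybar_j)^2 / (N (r - 1)) )`` -- the
    pooled within-sample replicate standard deviation.
    """
    table = np.atleast_2d(np.asarray(replicate_table, dtype=float))
    n, r = table.shape
    if r < 2:
        raise ValueError("need at least 2 replicates per sample")
    centered = table - table.mean(axis=1, keepdims=True)
    sel_val = float(np.sqrt(np.sum(centered**2) / (n * (r - 1))))
    sd_mean = float(np.mean(np.std(table, axis=1, ddof=1)))
    return SELResult(sel=sel_val, sd_mean=sd_mean, n_samples=n, n_replicates=r)


def qualify_model(report: ValidationReport, sel_result: SELResult) -> str:
    """Method-qualification verdict from R-squared and the RMSEP/SEL ratio.

    excellent: external R2 > 0.90 and RMSEP < 1.5 x SEL;
    good: R2 >= 0.70 and RMSEP <= 3 x SEL (covers the gap between the
    published bands); otherwise qualitative-only.  With SEL = 0 the ratio is
    undefined and the verdict falls back to R2 alone, with a warning.
    """
    if report.rmsep is None or report.r2_ext is None:
        raise ValueError("external validation results are required")
    r2, rmsep = report.r2_ext, report.rmsep
    if sel_result.sel == 0:
        warnings.warn("SEL is zero: RMSEP/SEL undefined, verdict from R2 only")
        return "excellent" if r2 > 0.90 else "good" if r2 >= 0.70 else "qualitative-only"
    ratio = rmsep / sel_result.sel
    if r2 > 0.90 and ratio < 1.5:
        return "excellent"
    if r2 >= 0.70 and ratio <= 3.0:
        return "good"
    return "qualitative-only"


# -- I/O ----------------------------------------------------------------------


def read_spectra(path: str | Path) -> SpectraSet:
    """Wide CSV: first column time_h, remaining headers wavelengths in nm."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.columns[0] != "time_h":
        raise ValueError("first column of a spectra CSV must be time_h")
    wl = np.array([float(c) for c in df.columns[1:]])
    return SpectraSet(wl, df.iloc[:, 1:].to_numpy(dtype=float),
                      df["time_h"].to_numpy(dtype=float))


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(spectra.absorbance, columns=[f"{w:g}" for w in spectra.wavelengths])
    df.insert(0, "time_h", spectra.times)
    df.to_csv(path, index=False)


def save_calibration(model: PLSCalibration, path: str | Path) -> None:
    doc = {
        "analyte": model.analyte,
        "window": list(model.window),
        "n_lv": model.n_lv,
        "preprocess": {
            "sg_window": model.preprocess_config.sg_window,
            "sg_polyorder": model.preprocess_config.sg_polyorder,
            "sg_derivative": model.preprocess_config.sg_derivative,
            "mean_center": model.preprocess_config.mean_center,
            "excluded_bands": [
                [lo, "inf" if np.isinf(hi) else hi]
                for lo, hi in model.preprocess_config.excluded_bands
            ],
        },
        "training_means": model.training_means.tolist(),
        "wavelengths": model.wavelengths.tolist(),
        "coef": model.coef.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "report": None if model.report is None else model.report.rounded(),
    }
    Path(path).write_text(json.dumps(doc))


def load_calibration(path: str | Path) -> PLSCalibration:
    doc = json.loads(Path(path).read_text())
    pp = doc["preprocess"]
    config = PreprocessConfig(
        sg_window=pp["sg_window"], sg_polyorder=pp["sg_polyorder"],
        sg_derivative=pp["sg_derivative"], mean_center=pp["mean_center"],
        excluded_bands=tuple(
            (lo, float("inf") if hi == "inf" else hi) for lo, hi in pp["excluded_bands"]
        ),
    )
    rep = doc.get("report")
    report = None
    if rep:
        report = ValidationReport(
            analyte=rep["analyte"], rmsec=rep["rmsec"], r2_cal=rep["r2_cal"],
            rmsecv=rep.get("rmsecv"), r2_cv=rep.get("r2_cv"),
            rmsep=rep.get("rmsep"), r2_ext=rep.get("r2_ext"),
            n_cal=rep.get("n_cal", 0), n_val=rep.get("n_val", 0),
        )
    return PLSCalibration(
        analyte=doc["analyte"], window=tuple(doc["window"]), n_lv=doc["n_lv"],
        preprocess_config=config,
        training_means=np.array(doc["training_means"]),
        wavelengths=np.array(doc["wavelengths"]),
        coef=np.array(doc["coef"]), x_mean=np.array(doc["x_mean"]),
        y_mean=doc["y_mean"], report=report,
    )
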