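"""Specific extracellular rates from chemostat time series.

At steady state the dilution rate ``D = F/V`` equals the specific growth
rate ``mu``; residual transients are picked up by the ``(1/X) dX/dt`` term.
Specific uptake/production rates follow the washout balance
``q = F (C_in - C_out) / (V X)`` and gas rates are the volumetric OUR/CER
divided by biomass.  Uncertainties are propagated to a full
variance-covariance matrix (rates sharing the biomass measurement are
correlated), which downstream metabolite balancing consumes as ``psi_b``.

Sign convention: uptake rates (glycerol, O2) and production rates (CO2,
biomass) are all reported positive; the exchange reactions of the network
are oriented so that positive rates plug in directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mfa import MeasuredFluxSet

__all__ = [
    "GLYCEROL_MOLAR_MASS",
    "ChemostatTimeSeries",
    "SteadyStateWindow",
    "ExtracellularRates",
    "read_series",
    "write_series",
    "specific_growth_rate",
    "specific_rate",
    "gas_specific_rates",
    "respiration_quotient",
    "detect_steady_state",
    "propagate_rate_errors",
    "estimate_state_rates",
    "build_measured_flux_set",
    "compare_rate_sets",
    "relative_flux",
]

GLYCEROL_MOLAR_MASS = 92.094  # g/mol

_CSV_COLUMNS = {
    "time": "time_h",
    "F": "F_L_per_h",
    "V": "V_L",
    "X": "X_gDCW_per_L",
    "S": "S_g_per_L",
    "OUR": "OUR_mmol_per_L_h",
    "CER": "CER_mmol_per_L_h",
}


@dataclass
class ChemostatTimeSeries:
    """Time-indexed process record of a chemostat culture.

    Channels: feed flow ``F`` (L/h), working volume ``V`` (L), biomass ``X``
    (gDCW/L), substrate ``S`` (g/L, glycerol), and volumetric gas rates
    ``OUR``/``CER`` (mmol/L/h).  ``sd`` optionally holds per-channel assay
    standard deviations (scalar per channel).
    """

    time: np.ndarray
    F: np.ndarray
    V: np.ndarray
    X: np.ndarray
    S: np.ndarray
    OUR: np.ndarray
    CER: np.ndarray
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time", "F", "V", "X", "S", "OUR", "CER"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        n = len(self.time)
        for name in ("F", "V", "X", "S", "OUR", "CER"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.V <= 0):
            raise ValueError("working volume must be positive")
        for name in ("X", "S"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"channel {name!r} has negative concentrations")

    def __len__(self) -> int:
        return len(self.time)

    def window(self, start: int, stop: int) -> "ChemostatTimeSeries":
        sl = slice(start, stop)
        return ChemostatTimeSeries(
            self.time[sl], self.F[sl], self.V[sl], self.X[sl], self.S[sl],
            self.OUR[sl], self.CER[sl], dict(self.sd),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({col: getattr(self, key) for key, col in _CSV_COLUMNS.items()})
        for key, val in self.sd.items():
            df[f"{_CSV_COLUMNS[key]}_sd"] = val
        return df


@dataclass(frozen=True)
class SteadyStateWindow:
    """Index range of a steady state within a series (inclusive, exclusive)."""

    label: str
    start: int
    stop: int
    D: float

    @property
    def n_points(self) -> int:
        return self.stop - self.start

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a steady-state window needs at least 2 points")


@dataclass
class ExtracellularRates:
    """Specific rates for one steady state, mmol/(gDCW h) (biomass in 1/h)."""

    label: str
    D: float
    mu: float
    q_gly: float
    q_o2: float
    q_co2: float
    psi: np.ndarray            # covariance over (q_gly, q_o2, q_co2, mu)
    rq: float
    yield_xs: float
    n_points: int
    x_bar: float = float("nan")  # mean biomass over the window, gDCW/L

    names: tuple[str, ...] = ("q_gly", "q_o2", "q_co2", "mu")

    @property
    def values(self) -> np.ndarray:
        return np.array([self.q_gly, self.q_o2, self.q_co2, self.mu])

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.psi), 0.0, None))


# -- I/O ----------------------------------------------------------------------


def read_series(path: str | Path) -> ChemostatTimeSeries:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS.values() if c not in df.columns]
    if missing:
        raise ValueError(f"series CSV missing columns: {missing}")
    sd = {}
    for key, col in _CSV_COLUMNS.items():
        if f"{col}_sd" in df.columns:
            sd[key] = float(df[f"{col}_sd"].iloc[0])
    return ChemostatTimeSeries(
        *(df[col].to_numpy(dtype=float) for col in _CSV_COLUMNS.values()), sd=sd
    )


def write_series(series: ChemostatTimeSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


# -- elementary rate operations ----------------------------------------------


def specific_growth_rate(
    window: SteadyStateWindow, series: ChemostatTimeSeries
) -> tuple[float, float]:
    """``mu = mean(F/V) + slope(X vs t)/mean(X)`` over the window, with sd.

    The derivative term is the least-squares slope of biomass against time;
    at a true steady state it vanishes.  Returns ``(mu, sd)``.
    """
    w = series.window(window.start, window.stop)
    if len(w) < 2:
        raise ValueError("window must contain at least 2 points")
    x_bar = float(np.mean(w.X))
    if x_bar == 0:
        raise ZeroDivisionError("mean biomass is zero")
    dil = w.F / w.V
    d_mean = float(np.mean(dil))
    slope, slope_var = _ls_slope(w.time, w.X)
    mu = d_mean + slope / x_bar

    n = len(w)
    var_d = float(np.var(dil, ddof=1)) / n if n > 1 else 0.0
    sd_x = w.sd.get("X", float(np.std(w.X, ddof=1)))
    var_xbar = sd_x**2 / n
    var_mu = var_d + slope_var / x_bar**2 + (slope**2 / x_bar**4) * var_xbar
    return mu, float(np.sqrt(var_mu))


def _ls_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and its sampling variance."""
    n = len(t)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    if sxx == 0:
        return 0.0, 0.0
    slope = float(tc @ y) / sxx
    if n > 2:
        resid = y - y.mean() - slope * tc
        s2 = float(resid @ resid) / (n - 2)
        return slope, s2 / sxx
    return slope, 0.0


def specific_rate(
    c_in: float,
    c_out: float,
    F: float,
    V: float,
    X: float,
    molar_mass: float | None = None,
) -> float:
    """``q = F (C_in - C_out) / (V X)``, in mmol/(g h) when a molar mass
    (g/mol) is given, else in g/(g h).

    With the inlet-minus-outlet ordering, substrate consumption comes out
    positive.  ``F = 0`` (batch operation) returns 0 with a warning: batch
    rates need the accumulation term this balance omits.
    """
    if V * X <= 0:
        raise ValueError("V * X must be positive")
    if F == 0:
        warnings.warn(
            "F = 0: the washout balance gives q = 0; batch rates require "
            "the accumulation term"
        )
    q = F * (c_in - c_out) / (V * X)
    if molar_mass is not None:
        q *= 1000.0 / molar_mass
    return q


def gas_specific_rates(OUR: float, CER: float, X: float) -> tuple[float, float]:
    """Volumetric gas rates (mmol/L/h) to specific rates (mmol/(g h)).

    Negative inputs are accepted and signify net production/consumption
    reversal."""
    if X <= 0:
        raise ValueError("biomass concentration must be positive")
    return OUR / X, CER / X


def respiration_quotient(CER: float, OUR: float) -> float:
    if OUR == 0:
        raise ZeroDivisionError("OUR is zero")
    return CER / OUR


# -- steady-state detection ---------------------------------------------------

#: Default time-invariance tolerances: ("rel", x) bounds the relative range
#: (max-min)/|mean|; ("abs", x) bounds the absolute range, used for the
#: residual substrate whose steady-state level sits below assay noise.
DEFAULT_TOLERANCES: dict[str, tuple[str, float]] = {
    "X": ("rel", 0.15),
    "S": ("abs", 9.0),
    "OUR": ("rel", 0.06),
    "CER": ("rel", 0.06),
}


def detect_steady_state(
    series: ChemostatTimeSeries,
    D: float,
    residence_times: float = 3.0,
    tolerances: Mapping[str, tuple[str, float]] | None = None,
    n_points: int = 6,
    label: str = "",
    d_rtol: float = 0.02,
) -> SteadyStateWindow | None:
    """Earliest window of ``n_points`` samples that is time-invariant.

    The segment at dilution rate ``D`` is located from the (noise-free)
    ``F/V`` channel; candidate windows start after ``residence_times / D``
    hours into the segment and must satisfy the per-channel tolerances on
    ``X``, ``S``, ``OUR`` and ``CER``.  Returns ``None`` if no window
    qualifies.
    """
    if D <= 0:
        raise ValueError("dilution rate must be positive")
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    dil = series.F / series.V
    in_state = np.abs(dil - D) <= d_rtol * D
    if not np.any(in_state):
        return None
    idx = np.where(in_state)[0]
    # first contiguous run at this dilution rate
    breaks = np.where(np.diff(idx) > 1)[0]
    run_end = idx[breaks[0]] + 1 if len(breaks) else idx[-1] + 1
    run_start = idx[0]
    t_ready = series.time[run_start] + residence_times / D
    for start in range(run_start, run_end - n_points + 1):
        if series.time[start] < t_ready:
            continue
        stop = start + n_points
        if _window_invariant(series, start, stop, tol):
            return SteadyStateWindow(label=label, start=start, stop=stop, D=float(
                np.mean(dil[start:stop])))
    return None


def _window_invariant(series, start, stop, tol) -> bool:
    for name, (kind, bound) in tol.items():
        y = getattr(series, name)[start:stop]
        rng = float(y.max() - y.min())
        if kind == "rel":
            mean = abs(float(y.mean()))
            if mean == 0:
                if rng > 0:
                    return False
            elif rng / mean >= bound:
                return False
        elif kind == "abs":
            if rng >= bound:
                return False
        else:
            raise ValueError(f"unknown tolerance kind {kind!r}")
    return True


# -- error propagation --------------------------------------------------------


def propagate_rate_errors(
    F: float, V: float, X: float, S_in: float, S_out: float,
    OUR: float, CER: float,
    sds: Mapping[str, float],
    molar_mass: float = GLYCEROL_MOLAR_MASS,
    slope_var: float = 0.0,
) -> np.ndarray:
    """First-order covariance of ``(q_gly, q_o2, q_co2, mu)``.

    ``sds`` holds standard deviations of the inputs under keys
    ``F, V, X, S_in, S_out, OUR, CER`` (missing keys mean exact).  The
    biomass measurement is shared by all four rates, which induces the
    off-diagonal covariance structure.  ``slope_var`` adds the sampling
    variance of the ``dX/dt`` term of ``mu`` (already divided by X^2 terms
    are handled internally).
    """
    for key, val in sds.items():
        if val < 0:
            raise ValueError(f"sd for {key!r} must be >= 0")
    k = 1000.0 / molar_mass
    q_gly = k * F * (S_in - S_out) / (V * X)
    theta = ["F", "V", "X", "S_in", "S_out", "OUR", "CER"]
    G = np.zeros((4, len(theta)))
    # q_gly
    G[0] = [q_gly / F if F else k * (S_in - S_out) / (V * X),
            -q_gly / V, -q_gly / X, k * F / (V * X), -k * F / (V * X), 0, 0]
    # q_o2, q_co2
    G[1] = [0, 0, -OUR / X**2, 0, 0, 1.0 / X, 0]
    G[2] = [0, 0, -CER / X**2, 0, 0, 0, 1.0 / X]
    # mu = F/V (+ slope/X term whose variance enters via slope_var)
    G[3] = [1.0 / V, -F / V**2, 0, 0, 0, 0, 0]
    sigma = np.diag([sds.get(name, 0.0) ** 2 for name in theta])
    psi = G @ sigma @ G.T
    psi[3, 3] += slope_var / X**2
    return 0.5 * (psi + psi.T)


def estimate_state_rates(
    series: ChemostatTimeSeries,
    window: SteadyStateWindow,
    S_in: float,
    molar_mass: float = GLYCEROL_MOLAR_MASS,
) -> ExtracellularRates:
    """Average the window into a single rate set with covariance.

    Window means feed the point estimates; the assay standard deviations
    (``series.sd``, falling back to the window sample sd) are reduced by
    ``sqrt(n)`` for the mean and propagated through the rate formulas.
    """
    w = series.window(window.start, window.stop)
    n = len(w)
    F, V, X = float(w.F.mean()), float(w.V.mean()), float(w.X.mean())
    S = float(w.S.mean())
    OUR, CER = float(w.OUR.mean()), float(w.CER.mean())

    mu, _ = specific_growth_rate(window, series)
    slope, slope_var = _ls_slope(w.time, w.X)
    q_gly = specific_rate(S_in, S, F, V, X, molar_mass=molar_mass)
    q_o2, q_co2 = gas_specific_rates(OUR, CER, X)

    def sem(channel: str, data: np.ndarray) -> float:
        sd = w.sd.get(channel, float(np.std(data, ddof=1)) if n > 1 else 0.0)
        return sd / np.sqrt(n)

    sds = {
        "F": float(np.std(w.F, ddof=1)) / np.sqrt(n) if n > 1 else 0.0,
        "V": 0.0,
        "X": sem("X", w.X),
        "S_in": 0.0,
        "S_out": sem("S", w.S),
        "OUR": sem("OUR", w.OUR),
        "CER": sem("CER", w.CER),
    }
    psi = propagate_rate_errors(F, V, X, S_in, S, OUR, CER, sds,
                                molar_mass=molar_mass, slope_var=slope_var)
    d_mean = float(np.mean(w.F / w.V))
    yield_xs = mu / (q_gly * molar_mass / 1000.0) if q_gly > 0 else float("nan")
    return ExtracellularRates(
        label=window.label, D=d_mean, mu=mu, q_gly=q_gly, q_o2=q_o2,
        q_co2=q_co2, psi=psi, rq=respiration_quotient(CER, OUR),
        yield_xs=yield_xs, n_points=n, x_bar=X,
    )


#: Mapping from rate names to the exchange reactions of the packaged network.
DEFAULT_RATE_REACTIONS = {"q_o2": "r36", "q_co2": "r37", "q_gly": "r40", "mu": "r44"}


def build_measured_flux_set(
    rates: ExtracellularRates,
    model,
    rate_reactions: Mapping[str, str] | None = None,
    zero_floor_frac: float = 0.01,
    diagonal: bool = True,
) -> MeasuredFluxSet:
    """Assemble the 9-member measured set for metabolite balancing.

    Products not detected in the broth (ethanol, succinate, acetate,
    pyruvate, citrate) enter as zero rates with a variance floor of
    ``(zero_floor_frac * q_gly)^2`` so the weight matrix stays invertible.
    ``diagonal=True`` (default) discards the measured covariances and keeps
    only variances.
    """
    rate_reactions = dict(rate_reactions or DEFAULT_RATE_REACTIONS)
    ids = list(model.measured_ids)
    r_b = np.zeros(len(ids))
    psi = np.zeros((len(ids), len(ids)))
    floor = (zero_floor_frac * rates.q_gly) ** 2
    name_by_rid = {rid: name for name, rid in rate_reactions.items()}
    rate_idx = {name: k for k, name in enumerate(rates.names)}
    psi_rates = np.diag(np.diag(rates.psi)) if diagonal else rates.psi
    for i, rid in enumerate(ids):
        name_i = name_by_rid.get(rid)
        if name_i is None:
            psi[i, i] = floor
            continue
        r_b[i] = rates.values[rate_idx[name_i]]
        for j, rid_j in enumerate(ids):
            name_j = name_by_rid.get(rid_j)
            if name_j is not None:
                psi[i, j] = psi_rates[rate_idx[name_i], rate_idx[name_j]]
    return MeasuredFluxSet(ids=ids, r_b=r_b, psi_b=psi)


# -- off-line vs on-line comparison -------------------------------------------


def compare_rate_sets(
    a: Mapping[str, tuple[float, float, int]],
    b: Mapping[str, tuple[float, float, int]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per rate between two rate sets.

    Each mapping gives ``name -> (mean, sd, n)``.  Returns a table with the
    t statistic, Welch degrees of freedom, p-value and a significance flag
    at ``alpha``.
    """
    if set(a) != set(b):
        raise ValueError("rate sets must cover the same rate names")
    rows = []
    for name in a:
        m1, s1, n1 = a[name]
        m2, s2, n2 = b[name]
        if s1 is None or s2 is None:
            raise ValueError(f"missing sd for rate {name!r}")
        se1, se2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(se1 + se2)
        if se == 0:
            t, df, p = 0.0, float(n1 + n2 - 2), 1.0
        else:
            t = (m1 - m2) / se
            df = (se1 + se2) ** 2 / (
                se1**2 / (n1 - 1) + se2**2 / (n2 - 1)
            )
            p = 2.0 * float(stats.t.sf(abs(t), df))
        rows.append({"rate": name, "t": t, "df": df, "p_value": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows)


def relative_flux(r_x: float, r_gly: float) -> float:
    """Flux as a signed percentage of the glycerol uptake flux."""
    if r_gly == 0:
        raise ZeroDivisionError("glycerol uptake flux is zero")
    return 100.0 * r_x / r_gly
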