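"""Synthetic study data with known ground truth.

Three generators stand in for the bioreactor, the off-line assays and the
in-situ spectrometer:

* a Monod chemostat simulator (batch phase followed by a schedule of
  dilution-rate steady states) whose off-gas rates are derived from the
  reaction network's carbon balance and a per-state respiration-quotient
  target, so that the emitted extracellular rates are exactly consistent
  with the stoichiometric model before noise is added;
* a Beer-Lambert mixture-spectra generator with analyte absorption bands,
  dominant water bands, time-dependent baseline drift and white noise;
* a flux-data generator that draws balanced flux vectors from the null
  space of the stoichiometric matrix and corrupts the measured rates with
  multivariate Gaussian noise -- the harness for calibration and coverage
  studies of the balancing estimator.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .mfa import MeasuredFluxSet
from .network import StoichiometricModel, load_pichia_network
from .nirs import SpectraSet
from .rates import GLYCEROL_MOLAR_MASS, ChemostatTimeSeries

__all__ = [
    "ChemostatConfig",
    "SpectraConfig",
    "FluxTruth",
    "SimulationResult",
    "simulate_chemostat",
    "generate_spectra",
    "spectra_for_simulation",
    "generate_flux_dataset",
]


@dataclass
class ChemostatConfig:
    """Process and noise settings of the simulated glycerol chemostat.

    Kinetics are Monod with constant yield (no maintenance by default: the
    observed yields vary too little across the studied dilution rates to
    identify one).  Off-line assay noise matches the reference-method
    repeatability (biomass 0.56 g/L, glycerol 2.20 g/L); gas analysis is
    much more precise and carries a small relative error.
    """

    mu_max: float = 0.17            # 1/h, max specific growth rate on glycerol
    Ks: float = 0.1                 # g/L, Monod half-saturation
    Y_XS: float = 0.65              # gDCW per g glycerol
    S_in: float = 40.0              # g/L glycerol in the feed
    V: float = 5.0                  # L working volume
    X0: float = 0.35                # gDCW/L at inoculation
    batch_hours: float = 27.0
    dilution_schedule: tuple[tuple[str, float, float], ...] = (
        ("A", 0.05, 100.0), ("B", 0.10, 60.0), ("C", 0.15, 45.0),
    )                               # (label, D in 1/h, duration in h)
    offline_interval: float = 4.0   # h between off-line samples
    spectra_interval: float = 0.5   # h between spectra
    sd_X: float = 0.56              # g/L, dry-cell-weight assay sd
    sd_S: float = 2.20              # g/L, glycerol assay sd
    gas_rel_sd: float = 0.005       # relative sd of OUR/CER
    rq_targets: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.33, "B": 0.36, "C": 0.40}
    )
    maintenance: float = 0.0        # g glycerol per gDCW per h, optional
    seed: int = 0


@dataclass
class SimulationResult:
    config: ChemostatConfig
    series: ChemostatTimeSeries          # noisy off-line record
    true_series: ChemostatTimeSeries     # same timestamps, noise-free
    fine_times: np.ndarray               # spectra cadence
    fine_X: np.ndarray
    fine_S: np.ndarray
    fine_OUR: np.ndarray
    fine_CER: np.ndarray
    schedule: list[tuple[str, float, float, float]]  # label, D, t0, t1


def _carbon_constraint(model: StoichiometricModel) -> dict[str, float]:
    """Coefficients of the single redundant equation on the measured rates.

    The internal reactions of the packaged network conserve exactly one
    quantity (carbon), so the left null space of ``An`` is one-dimensional
    and ``w @ Ab`` gives the carbon numbers of the exchanged species.
    """
    An, Ab = model.partition()
    W = null_space(An.T)
    if W.shape[1] != 1:
        raise ValueError(
            f"expected exactly one redundant equation, found {W.shape[1]}"
        )
    w = W[:, 0]
    coefs = w @ Ab
    # normalize so the glycerol-uptake coefficient is positive
    ids = model.measured_ids
    if "r40" in ids and coefs[ids.index("r40")] < 0:
        coefs = -coefs
    return dict(zip(ids, coefs))


def gas_rate_coefficients(
    model: StoichiometricModel, rq: float
) -> tuple[float, float, float, float]:
    """Linear maps (a_gly, a_mu) such that q_co2 = a_gly q_gly + a_mu mu,
    and the corresponding q_o2 factors via the respiration quotient."""
    c = _carbon_constraint(model)
    # c_gly*q_gly + c_co2*q_co2 + c_biom*mu = 0 with all products at zero
    a_gly = -c["r40"] / c["r37"]
    a_mu = -c["r44"] / c["r37"]
    return a_gly, a_mu, a_gly / rq, a_mu / rq


def simulate_chemostat(
    config: ChemostatConfig = ChemostatConfig(),
    model: StoichiometricModel | None = None,
) -> SimulationResult:
    """Integrate the batch + multi-state chemostat and sample it.

    ``dX/dt = (mu - D) X``, ``dS/dt = D (S_in - S) - mu X / Y_XS - m X``
    with Monod ``mu``; during the batch phase ``D = 0``.  OUR and CER come
    from the network carbon balance at the instantaneous ``q_gly`` and
    ``mu``, scaled to the per-state respiration-quotient target.  Off-line
    samples carry truncated Gaussian assay noise; the gas channels carry
    relative noise.
    """
    model = model or load_pichia_network()
    for label, D, _ in config.dilution_schedule:
        if D >= config.mu_max:
            raise ValueError(
                f"state {label}: D = {D} exceeds mu_max = {config.mu_max} "
                "(washout must be requested explicitly)"
            )
        if D <= 0:
            raise ValueError(f"state {label}: D must be positive")

    def rhs(D):
        def f(t, y):
            X, S = y
            mu = config.mu_max * S / (config.Ks + S) if S > 0 else 0.0
            dX = (mu - D) * X
            dS = D * (config.S_in - S) - mu * X / config.Y_XS \
                - config.maintenance * X
            return [dX, dS]
        return f

    phases = [("batch", 0.0, config.batch_hours)] + [
        (label, D, dur) for label, D, dur in config.dilution_schedule
    ]
    t0 = 0.0
    y = [config.X0, config.S_in]
    fine_t, fine_X, fine_S, fine_D = [], [], [], []
    schedule = []
    for label, D, dur in phases:
        t1 = t0 + dur
        t_eval = np.arange(t0, t1, config.spectra_interval)
        sol = solve_ivp(rhs(D), (t0, t1), y, t_eval=t_eval, method="LSODA",
                        rtol=1e-9, atol=1e-10, max_step=1.0)
        fine_t.append(sol.t)
        fine_X.append(np.clip(sol.y[0], 0.0, None))
        fine_S.append(np.clip(sol.y[1], 0.0, None))
        fine_D.append(np.full_like(sol.t, D))
        if label != "batch":
            schedule.append((label, D, t0, t1))
        end = solve_ivp(rhs(D), (t0, t1), y, method="LSODA",
                        rtol=1e-9, atol=1e-10, max_step=1.0)
        y = [float(end.y[0, -1]), float(end.y[1, -1])]
        t0 = t1
    fine_t = np.concatenate(fine_t)
    fine_X = np.concatenate(fine_X)
    fine_S = np.concatenate(fine_S)
    fine_D = np.concatenate(fine_D)

    # instantaneous specific rates and network-consistent gas rates
    mu_t = config.mu_max * fine_S / (config.Ks + fine_S)
    q_gly_g = mu_t / config.Y_XS + config.maintenance   # g/(g h)
    q_gly = q_gly_g * 1000.0 / GLYCEROL_MOLAR_MASS      # mmol/(g h)
    rq_by_label = dict(config.rq_targets)
    first_rq = rq_by_label.get(config.dilution_schedule[0][0], 0.36)
    rq_t = np.full_like(fine_t, first_rq)
    for label, D, a, b in schedule:
        rq_t[(fine_t >= a) & (fine_t < b)] = rq_by_label.get(label, first_rq)
    c = _carbon_constraint(model)
    a_gly = -c["r40"] / c["r37"]
    a_mu = -c["r44"] / c["r37"]
    q_co2 = a_gly * q_gly + a_mu * mu_t
    q_o2 = q_co2 / rq_t
    fine_OUR = q_o2 * fine_X
    fine_CER = q_co2 * fine_X

    # off-line sampling with assay noise
    rng = np.random.default_rng(config.seed)
    stride = max(1, int(round(config.offline_interval / config.spectra_interval)))
    idx = np.arange(0, len(fine_t), stride)
    t_s = fine_t[idx]
    F_s = fine_D[idx] * config.V
    V_s = np.full_like(t_s, config.V)
    X_true, S_true = fine_X[idx], fine_S[idx]
    OUR_true, CER_true = fine_OUR[idx], fine_CER[idx]
    X_obs = np.clip(X_true + rng.normal(0.0, config.sd_X, len(idx)), 0.0, None)
    S_obs = np.clip(S_true + rng.normal(0.0, config.sd_S, len(idx)), 0.0, None)
    OUR_obs = OUR_true * (1.0 + rng.normal(0.0, config.gas_rel_sd, len(idx)))
    CER_obs = CER_true * (1.0 + rng.normal(0.0, config.gas_rel_sd, len(idx)))
    gas_sd = config.gas_rel_sd * float(np.median(OUR_true[OUR_true > 0])) \
        if np.any(OUR_true > 0) else 0.0
    cer_sd = config.gas_rel_sd * float(np.median(CER_true[CER_true > 0])) \
        if np.any(CER_true > 0) else 0.0
    sd = {"X": config.sd_X, "S": config.sd_S, "OUR": gas_sd, "CER": cer_sd}
    series = ChemostatTimeSeries(t_s, F_s, V_s, X_obs, S_obs, OUR_obs, CER_obs, sd)
    true_series = ChemostatTimeSeries(
        t_s, F_s, V_s, X_true, S_true, OUR_true, CER_true,
        {"X": 0.0, "S": 0.0, "OUR": 0.0, "CER": 0.0},
    )
    return SimulationResult(
        config=config, series=series, true_series=true_series,
        fine_times=fine_t, fine_X=fine_X, fine_S=fine_S,
        fine_OUR=fine_OUR, fine_CER=fine_CER, schedule=schedule,
    )


# -- spectra ------------------------------------------------------------------


@dataclass
class SpectraConfig:
    """Beer-Lambert mixture-spectra settings.

    Band amplitudes are absorbance units per g/L at 1 mm path length;
    Gaussian band shapes.  The biomass bands sit in the -CH second-overtone
    region (1250-1350 nm); glycerol absorbs across 1500-1800 nm (-OH
    stretch and -CH combination bands).  Large water bands at 1400 and
    1900 nm and a slow wavelength-dependent baseline drift emulate the raw
    in-situ signal.
    """

    grid_start: float = 800.0
    grid_stop: float = 2200.0
    grid_step: float = 2.0
    biomass_bands: tuple[tuple[float, float, float], ...] = (
        (1280.0, 22.0, 0.0060), (1330.0, 18.0, 0.0040),
    )
    glycerol_bands: tuple[tuple[float, float, float], ...] = (
        (1580.0, 40.0, 0.0035), (1695.0, 25.0, 0.0050), (1735.0, 30.0, 0.0030),
    )
    water_bands: tuple[tuple[float, float, float], ...] = (
        (1400.0, 35.0, 0.90), (1905.0, 45.0, 1.40),
    )
    baseline_drift_per_h: float = 1.5e-3   # AU/h at the long-wavelength end
    noise_sd: float = 2.0e-4               # AU, white noise per channel
    path_length: float = 1.0               # relative transflectance factor
    seed: int = 0

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + 0.5 * self.grid_step,
                         self.grid_step)


def _gaussian_bands(wl: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wl)
    for center, width, amp in bands:
        out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def generate_spectra(
    times: np.ndarray,
    biomass: np.ndarray,
    glycerol: np.ndarray,
    config: SpectraConfig = SpectraConfig(),
) -> SpectraSet:
    """Mixture spectra for concentration trajectories.

    ``A(t, l) = path * (X(t) s_X(l) + S(t) s_S(l)) + water(l)
    + drift(t) b(l) + noise`` with ``b(l)`` rising linearly across the
    grid, emulating detector drift toward saturation with process time.
    """
    times = np.asarray(times, dtype=float)
    wl = config.wavelengths
    s_x = _gaussian_bands(wl, config.biomass_bands)
    s_s = _gaussian_bands(wl, config.glycerol_bands)
    water = _gaussian_bands(wl, config.water_bands)
    b = (wl - wl[0]) / (wl[-1] - wl[0])
    rng = np.random.default_rng(config.seed)
    A = config.path_length * (
        np.outer(np.asarray(biomass, dtype=float), s_x)
        + np.outer(np.asarray(glycerol, dtype=float), s_s)
    )
    A += water[None, :]
    A += config.baseline_drift_per_h * np.outer(times, b)
    A += rng.normal(0.0, config.noise_sd, A.shape)
    return SpectraSet(wl, A, times)


def spectra_for_simulation(
    sim: SimulationResult, config: SpectraConfig = SpectraConfig()
) -> SpectraSet:
    """Spectra at the simulator's fine (spectral) cadence."""
    return generate_spectra(sim.fine_times, sim.fine_X, sim.fine_S, config)


# -- flux datasets ------------------------------------------------------------


@dataclass
class FluxTruth:
    """A balanced ground-truth flux vector and its measured restriction."""

    reaction_ids: list[str]
    r: np.ndarray
    measured_ids: list[str]
    r_b: np.ndarray
    psi_b: np.ndarray
    seed: int

    def flux(self, rid: str) -> float:
        return float(self.r[self.reaction_ids.index(rid)])


def generate_flux_dataset(
    model: StoichiometricModel,
    n: int,
    psi_b: np.ndarray | None = None,
    seed: int = 0,
    measured_ids: Sequence[str] | None = None,
    rel_sd: float = 0.05,
    sd_floor: float = 1e-3,
) -> tuple[list[MeasuredFluxSet], FluxTruth]:
    """Noisy measurement replicates around one balanced flux vector.

    The truth is a random combination of the null-space basis of ``A``
    (8-dimensional for the packaged network), so ``A @ r = 0`` holds to
    machine precision.  Measured rates are the truth restricted to the
    measured reactions plus multivariate Gaussian noise with covariance
    ``psi_b`` (default: diagonal, ``rel_sd`` of each true rate with an
    absolute floor).
    """
    rng = np.random.default_rng(seed)
    measured_ids = list(measured_ids or model.measured_ids)
    A = model.A
    N = null_space(A)
    z = rng.standard_normal(N.shape[1])
    r = N @ z
    scale = np.max(np.abs(r))
    if scale > 0:
        r = r / scale  # O(1) fluxes
    ids = model.reaction_ids
    r_b = np.array([r[ids.index(rid)] for rid in measured_ids])
    if psi_b is None:
        sd = np.maximum(rel_sd * np.abs(r_b), sd_floor)
        psi_b = np.diag(sd**2)
    psi_b = np.asarray(psi_b, dtype=float)
    truth = FluxTruth(reaction_ids=ids, r=r, measured_ids=measured_ids,
                      r_b=r_b, psi_b=psi_b, seed=seed)
    chol = np.linalg.cholesky(psi_b + 1e-18 * np.eye(len(r_b)))
    datasets = [
        MeasuredFluxSet(
            ids=measured_ids,
            r_b=r_b + chol @ rng.standard_normal(len(r_b)),
            psi_b=psi_b,
        )
        for _ in range(n)
    ]
    return datasets, truth
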