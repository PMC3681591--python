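"""Weighted least-squares metabolite balancing with gross-error detection.

Given the pseudo-steady-state constraint ``An @ rn + Ab @ rb = 0`` with
measured extracellular rates ``rb`` (covariance ``psi_b``) and unknown
intracellular fluxes ``rn``, the estimator follows the classical
measurement-reconciliation scheme:

1. the redundancy matrix ``R = Ab - An @ pinv(An) @ Ab`` maps measurements
   onto the constraints they must satisfy on their own;
2. residuals ``e = -R @ rb`` are tested with the consistency index
   ``h = e' @ pinv(J) @ e``, ``J = R @ psi_b @ R'``, against a chi-square
   quantile with ``df = rank(R)`` -- a significant ``h`` flags gross
   measurement errors or wrong assumed biochemistry;
3. measurements are reconciled by the minimum-variance projection onto the
   constraint manifold, and the unknown fluxes follow by a pseudo-inverse
   solve, with covariances propagated linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MeasuredFluxSet",
    "FluxEstimate",
    "ConsistencyResult",
    "redundancy_matrix",
    "residuals",
    "chi2_critical",
    "consistency_index",
    "estimate_fluxes",
    "flux_report",
]


# Relative singular-value cutoff for pseudo-inverses and rank decisions.
# The redundancy matrix is itself the output of a pseudo-inverse projection,
# so its spurious singular values scale with eps * cond(An) rather than
# plain machine epsilon; 1e-10 separates them cleanly from genuine
# constraint directions for any reasonably scaled network.
_RCOND = 1e-10


def _pinv(M: np.ndarray) -> np.ndarray:
    if M.size == 0:
        return np.zeros((M.shape[1], M.shape[0]))
    return np.linalg.pinv(M, rcond=_RCOND)


def _rank(M: np.ndarray) -> int:
    if M.size == 0 or not np.any(M):
        return 0
    smax = float(np.linalg.norm(M, 2))
    return int(np.linalg.matrix_rank(M, tol=_RCOND * smax))


@dataclass
class MeasuredFluxSet:
    """Named extracellular rates with their variance-covariance matrix."""

    ids: list[str]
    r_b: np.ndarray
    psi_b: np.ndarray

    def __post_init__(self) -> None:
        self.r_b = np.asarray(self.r_b, dtype=float).ravel()
        self.psi_b = np.atleast_2d(np.asarray(self.psi_b, dtype=float))
        k = len(self.ids)
        if len(set(self.ids)) != k:
            raise ValueError("measured flux ids must be unique")
        if self.r_b.shape != (k,) or self.psi_b.shape != (k, k):
            raise ValueError("ids, r_b and psi_b dimensions do not agree")
        if not np.allclose(self.psi_b, self.psi_b.T):
            raise ValueError("psi_b must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.psi_b).min())
        if eigmin < -1e-10 * max(1.0, float(np.abs(self.psi_b).max())):
            raise ValueError("psi_b must be positive semidefinite")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.psi_b), 0.0, None))


@dataclass
class ConsistencyResult:
    h: float
    df: int
    chi2_critical: float
    alpha: float
    passed: bool
    e: np.ndarray
    R: np.ndarray
    J: np.ndarray

    @property
    def verdict(self) -> str:
        return "pass" if self.passed else "fail"


@dataclass
class FluxEstimate:
    unknown_ids: list[str]
    measured_ids: list[str]
    r_n: np.ndarray
    r_b_adjusted: np.ndarray
    psi_n: np.ndarray
    psi_b_adjusted: np.ndarray
    consistency: ConsistencyResult | None = None
    r_b_raw: np.ndarray | None = None

    @property
    def sd_n(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.psi_n), 0.0, None))

    @property
    def sd_b(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.psi_b_adjusted), 0.0, None))

    def flux(self, rid: str) -> float:
        if rid in self.unknown_ids:
            return float(self.r_n[self.unknown_ids.index(rid)])
        return float(self.r_b_adjusted[self.measured_ids.index(rid)])


def redundancy_matrix(An: np.ndarray, Ab: np.ndarray) -> np.ndarray:
    """``R = Ab - An @ pinv(An) @ Ab``; its rows span the measurement-space
    constraints and ``rank(R)`` is the df of the consistency test."""
    An = np.atleast_2d(np.asarray(An, dtype=float))
    Ab = np.atleast_2d(np.asarray(Ab, dtype=float))
    if An.shape[1] == 0:
        return Ab.copy()
    return Ab - An @ (_pinv(An) @ Ab)


def residuals(R: np.ndarray, r_b: np.ndarray) -> np.ndarray:
    """Deviation of the measured rates from the balance constraints."""
    return -np.atleast_2d(R) @ np.asarray(r_b, dtype=float).ravel()


def chi2_critical(alpha: float, df: int) -> float:
    """(1 - alpha) quantile of the chi-square distribution with ``df`` dof."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def consistency_index(
    e: np.ndarray,
    R: np.ndarray,
    psi_b: np.ndarray,
    alpha: float = 0.05,
) -> ConsistencyResult:
    """Gross-error test statistic ``h = e' pinv(J) e`` with ``J = R psi_b R'``.

    ``h`` is compared against the chi-square quantile at ``1 - alpha`` with
    ``df = rank(R)``.  A rank-0 redundancy matrix (exactly determined
    system) yields ``h = 0`` and a trivial pass, with a warning.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    e = np.asarray(e, dtype=float).ravel()
    psi_b = np.atleast_2d(np.asarray(psi_b, dtype=float))
    df = _rank(R)
    J = R @ psi_b @ R.T
    if df == 0:
        warnings.warn("redundancy matrix has rank 0: consistency test is vacuous")
        return ConsistencyResult(h=0.0, df=0, chi2_critical=float("nan"),
                                 alpha=alpha, passed=True, e=e, R=R, J=J)
    h = float(e @ (_pinv(J) @ e))
    crit = chi2_critical(alpha, df)
    return ConsistencyResult(h=h, df=df, chi2_critical=crit, alpha=alpha,
                             passed=h <= crit, e=e, R=R, J=J)


def estimate_fluxes(
    model,
    measured: MeasuredFluxSet,
    alpha: float = 0.05,
) -> FluxEstimate:
    """Reconcile the measured rates and solve for the unknown fluxes.

    The measurements are projected onto the constraint manifold by the
    minimum-variance (weighted least squares) adjustment

        r_b' = (I - psi_b R' pinv(R psi_b R') R) r_b

    after which the balance is satisfiable exactly and

        r_n = -pinv(An) Ab r_b'.

    Covariances are propagated through both linear maps.  Raises if ``An``
    is rank deficient (undetermined flux directions are reported via a
    null-space basis).
    """
    An, Ab = model.partition(measured.ids)
    unknown_ids = model.unknown_ids(measured.ids)
    if _rank(An) < An.shape[1]:
        from scipy.linalg import null_space

        ns = null_space(An)
        directions = []
        for k in range(ns.shape[1]):
            v = ns[:, k]
            big = np.abs(v) > 1e-8
            directions.append(
                " + ".join(f"{v[i]:+.3f}*{unknown_ids[i]}" for i in np.where(big)[0])
            )
        raise np.linalg.LinAlgError(
            "unknown-flux matrix An is rank deficient; undetermined directions: "
            + "; ".join(directions)
        )

    R = redundancy_matrix(An, Ab)
    e = residuals(R, measured.r_b)
    consistency = consistency_index(e, R, measured.psi_b, alpha=alpha)

    psi_b = measured.psi_b
    J_pinv = _pinv(R @ psi_b @ R.T)
    # I - psi_b R' pinv(J) R : oblique projector onto the constraint manifold
    P = np.eye(len(measured.ids)) - psi_b @ R.T @ J_pinv @ R
    r_b_adj = P @ measured.r_b
    psi_b_adj = P @ psi_b @ P.T

    An_pinv = _pinv(An)
    G = -An_pinv @ Ab  # r_n = G @ r_b_adjusted
    r_n = G @ r_b_adj
    psi_n = G @ psi_b_adj @ G.T

    return FluxEstimate(
        unknown_ids=unknown_ids,
        measured_ids=list(measured.ids),
        r_n=r_n,
        r_b_adjusted=r_b_adj,
        psi_n=psi_n,
        psi_b_adjusted=psi_b_adj,
        consistency=consistency,
        r_b_raw=measured.r_b.copy(),
    )


def flux_report(
    estimate: FluxEstimate,
    consistency: ConsistencyResult | None = None,
    glycerol_flux_id: str | None = "r40",
    reaction_order: Sequence[str] | None = None,
):
    """Per-reaction flux table (flux, sd, relative flux vs glycerol uptake).

    Returns a pandas DataFrame; negative fluxes carry a note that the
    reaction operates in the reverse direction.  If the glycerol uptake id
    is absent the relative-flux column is omitted with a warning.
    """
    import pandas as pd

    consistency = consistency or estimate.consistency
    ids = list(estimate.unknown_ids) + list(estimate.measured_ids)
    flux = np.concatenate([estimate.r_n, estimate.r_b_adjusted])
    sd = np.concatenate([estimate.sd_n, estimate.sd_b])
    kind = ["estimated"] * len(estimate.unknown_ids) + ["measured"] * len(
        estimate.measured_ids
    )
    df = pd.DataFrame({"reaction": ids, "flux": flux, "sd": sd, "kind": kind})
    if reaction_order is not None:
        order = {rid: k for k, rid in enumerate(reaction_order)}
        df = df.sort_values("reaction", key=lambda s: s.map(lambda r: order.get(r, 1e9)))
        df = df.reset_index(drop=True)

    if glycerol_flux_id is not None and glycerol_flux_id in ids:
        r_gly = estimate.flux(glycerol_flux_id)
        if r_gly == 0:
            warnings.warn("glycerol uptake flux is zero: relative fluxes omitted")
        else:
            df["relative_flux_pct"] = 100.0 * df["flux"] / r_gly
    elif glycerol_flux_id is not None:
        warnings.warn(
            f"glycerol flux id {glycerol_flux_id!r} not in estimate: "
            "relative fluxes omitted"
        )
    df["note"] = np.where(df["flux"] < 0, "operating in reverse direction", "")
    if consistency is not None:
        df.attrs["consistency"] = {
            "h": consistency.h, "df": consistency.df,
            "chi2_critical": consistency.chi2_critical,
            "alpha": consistency.alpha, "verdict": consistency.verdict,
        }
    return df
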