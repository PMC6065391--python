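"""Forward equilibrium solving and inverse rate design.

Forward: given rates ``(rho, mu)``, the unique interior equilibrium of
the competition model is ``R* = (C^T)^{-1} mu / eps`` and
``S* = [diag(R*) C]^{-1} rho``; with production it becomes
``R* = (C^T)^{-1} (P^T 1 + mu) / eps`` and
``S* = [diag(R*) C - P]^{-1} rho``.

Inverse: for *any* positive target densities ``(R*, S*)`` there exist
rates ``mu = eps C^T R* - P^T 1`` and ``rho = diag(R*) C S* - P S*``
that realise them.  With ``P = 0`` and nonnegative invertible ``C``
these rates are automatically positive — any feasible point of density
space can be made an equilibrium — while with production the positivity
has to be checked and is reported through :class:`FeasibilityWarning`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .dynamics import competition_rhs, crossfeeding_rhs
from .params import (
    CommunityParameters,
    DegenerateEquilibriumError,
    DimensionError,
    FeasibilityWarning,
    RankError,
    SpecialistCommunity,
    State,
)

logger = logging.getLogger(__name__)

#: condition number beyond which a matrix is treated as singular
CONDITION_LIMIT = 1e12

#: residual tolerance certifying an equilibrium solve
RESIDUAL_TOLERANCE = 1e-8

#: equilibria with densities below this are feasible but logged
NEAR_ZERO_DENSITY = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """Equilibrium densities with a strict-positivity feasibility flag
    and the max-absolute ODE residual at the solution."""

    R_star: NDArray[np.float64]
    S_star: NDArray[np.float64]
    feasible: bool
    residual: float


@dataclass(frozen=True)
class FeasibilityReport:
    """Per-index verdicts for the two specialist feasibility constraints.

    ``mortality_ok[i]`` is ``c r eps > sum_j (P^T)_ij`` (the column sum
    of ``P`` for consumer ``i``; needed for positive mortality rates)
    and ``influx_ok[i]`` is ``c r > sum_j P_ij`` (the row sum for
    resource ``i``; needed for positive influx rates).
    """

    mortality_ok: NDArray[np.bool_]
    influx_ok: NDArray[np.bool_]

    @property
    def all_ok(self) -> bool:
        return bool(self.mortality_ok.all() and self.influx_ok.all())

    @property
    def violating_mortality(self) -> NDArray[np.intp]:
        return np.flatnonzero(~self.mortality_ok)

    @property
    def violating_influx(self) -> NDArray[np.intp]:
        return np.flatnonzero(~self.influx_ok)


def _require_invertible(M: NDArray[np.float64], name: str) -> None:
    if M.shape[0] != M.shape[1]:
        raise DimensionError(f"{name} must be square, got shape {M.shape}")
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise RankError(
            f"{name} is singular or ill-conditioned (condition number {cond:.3e} "
            f"> {CONDITION_LIMIT:.0e})"
        )


def _finalize(params: CommunityParameters, R, S, rhs) -> Equilibrium:
    st = State.__new__(State)
    object.__setattr__(st, "R", R)
    object.__setattr__(st, "S", S)
    object.__setattr__(st, "t", 0.0)
    dR, dS = rhs(st, params)
    residual = float(max(np.abs(dR).max(), np.abs(dS).max()))
    feasible = bool(min(R.min(), S.min()) > 0)
    if feasible and min(R.min(), S.min()) < NEAR_ZERO_DENSITY:
        logger.warning(
            "equilibrium feasible but nearly degenerate: min density %.3e",
            min(R.min(), S.min()),
        )
    return Equilibrium(R_star=R, S_star=S, feasible=feasible, residual=residual)


def competitive_equilibrium(params: CommunityParameters) -> Equilibrium:
    """Interior equilibrium of the competition model (``P`` must be zero)."""
    if params.has_production:
        raise ValueError(
            "competitive_equilibrium requires P = 0; use crossfeeding_equilibrium"
        )
    _require_invertible(params.C, "C")
    R_star = np.linalg.solve(params.C.T, params.mu / params.epsilon)
    if np.any(np.abs(R_star) < np.finfo(float).tiny * 1e4):
        raise DegenerateEquilibriumError(
            "an equilibrium resource density is zero; consumer abundances undefined"
        )
    A = R_star[:, None] * params.C
    _require_invertible(A, "diag(R*) C")
    S_star = np.linalg.solve(A, params.rho)
    return _finalize(params, R_star, S_star, competition_rhs)


def crossfeeding_equilibrium(params: CommunityParameters) -> Equilibrium:
    """Interior equilibrium of the crossfeeding model."""
    _require_invertible(params.C, "C")
    col_load = params.P.sum(axis=0)  # total leakage per consumer
    R_star = np.linalg.solve(params.C.T, (col_load + params.mu) / params.epsilon)
    A = R_star[:, None] * params.C - params.P
    _require_invertible(A, "diag(R*) C - P")
    S_star = np.linalg.solve(A, params.rho)
    return _finalize(params, R_star, S_star, crossfeeding_rhs)


def rates_from_densities(
    C: ArrayLike,
    R_star: ArrayLike,
    S_star: ArrayLike,
    epsilon: float = 1.0,
    P: ArrayLike | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Influx and mortality rates ``(rho, mu)`` making ``(R*, S*)`` an
    equilibrium.

    Accepts rectangular ``C`` (``N_R x N_S`` with ``N_R >= N_S``): the
    inverse design is well posed for any shape, unlike the forward
    solve.  With ``P != 0`` a nonpositive designed rate raises a
    :class:`FeasibilityWarning` identifying the violating indices.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    R_star = np.atleast_1d(np.asarray(R_star, dtype=float))
    S_star = np.atleast_1d(np.asarray(S_star, dtype=float))
    if np.any(R_star <= 0) or np.any(S_star <= 0):
        raise ValueError("target densities must be entrywise positive")
    if R_star.shape[0] != C.shape[0] or S_star.shape[0] != C.shape[1]:
        raise DimensionError(
            f"C shape {C.shape} inconsistent with densities "
            f"({R_star.shape[0]}, {S_star.shape[0]})"
        )
    P = np.zeros_like(C) if P is None else np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape != C.shape:
        raise DimensionError(f"P shape {P.shape} != C shape {C.shape}")
    mu = epsilon * (C.T @ R_star) - P.sum(axis=0)
    rho = R_star * (C @ S_star) - P @ S_star
    if np.any(P != 0) and (np.any(mu <= 0) or np.any(rho <= 0)):
        warnings.warn(
            FeasibilityWarning(
                "designed rates are not all positive: "
                f"mu <= 0 at consumers {np.flatnonzero(mu <= 0).tolist()}, "
                f"rho <= 0 at resources {np.flatnonzero(rho <= 0).tolist()}"
            ),
            stacklevel=2,
        )
    return rho, mu


def specialist_rates(
    comm: SpecialistCommunity,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Rates ``(rho, mu)`` tuning a specialist community to its uniform
    equilibrium: ``mu = c r eps 1 - P^T 1`` and ``rho = s [c r I - P] 1``."""
    n = comm.n
    mu = comm.c * comm.r * comm.epsilon * np.ones(n) - comm.P.sum(axis=0)
    rho = comm.s * (comm.c * comm.r * np.ones(n) - comm.P.sum(axis=1))
    return rho, mu


def specialist_feasibility_constraints(comm: SpecialistCommunity) -> FeasibilityReport:
    """Check the two constraints under which the uniform specialist
    equilibrium is reachable with positive rates."""
    crn = comm.c * comm.r
    return FeasibilityReport(
        mortality_ok=crn * comm.epsilon > comm.P.sum(axis=0),
        influx_ok=crn > comm.P.sum(axis=1),
    )


def specialist_parameters(comm: SpecialistCommunity) -> CommunityParameters:
    """Full :class:`CommunityParameters` for a specialist community,
    with rates from :func:`specialist_rates`."""
    rho, mu = specialist_rates(comm)
    return CommunityParameters(
        C=comm.C, P=comm.P, rho=rho, mu=mu, epsilon=comm.epsilon
    )
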