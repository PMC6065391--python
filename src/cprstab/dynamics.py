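"""Right-hand sides of the community ODEs and trajectory simulation.

Two mass-action models are provided.  Pure competition for
substitutable abiotic resources::

    dR_i/dt = rho_i - eta_i R_i - R_i sum_j C_ij S_j
    dS_i/dt = eps S_i sum_j (C^T)_ij R_j - mu_i S_i

and the crossfeeding extension, in which consumers also produce
resources at density-dependent (but substrate-independent) rates and
pay the corresponding biomass cost::

    dR_i/dt = rho_i - eta_i R_i - R_i sum_j C_ij S_j + sum_j P_ij S_j
    dS_i/dt = eps S_i sum_j (C^T)_ij R_j - S_i sum_j (P^T)_ij - mu_i S_i

The production cost enters without an efficiency factor and without any
resource dependence: leakage is proportional to consumer density alone.
"""

from __future__ import annotations

import logging
from typing import Callable, Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

from .params import CommunityParameters, SimulationError, State, Trajectory

logger = logging.getLogger(__name__)

#: magnitude below which negative densities produced by the integrator
#: are treated as roundoff and clamped to zero
NEGATIVITY_TOLERANCE = 1e-12

RHSKind = Literal["competition", "crossfeeding"]


def competition_rhs(
    state: State, params: CommunityParameters
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Time derivatives ``(dR, dS)`` of the competition model.

    Ignores ``params.P``; use :func:`crossfeeding_rhs` for production.
    """
    state.check_shapes(params)
    R, S = state.R, state.S
    dR = params.rho - params.eta * R - R * (params.C @ S)
    dS = S * (params.epsilon * (params.C.T @ R) - params.mu)
    return dR, dS


def crossfeeding_rhs(
    state: State, params: CommunityParameters
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Time derivatives ``(dR, dS)`` of the crossfeeding model.

    Reduces exactly to :func:`competition_rhs` when ``params.P`` is zero.
    """
    state.check_shapes(params)
    R, S = state.R, state.S
    dR = params.rho - params.eta * R - R * (params.C @ S) + params.P @ S
    production_cost = params.P.sum(axis=0)  # column sums of P, one per consumer
    dS = S * (params.epsilon * (params.C.T @ R) - production_cost - params.mu)
    return dR, dS


_RHS_BY_NAME: dict[str, Callable] = {
    "competition": competition_rhs,
    "crossfeeding": crossfeeding_rhs,
}


def simulate(
    params: CommunityParameters,
    initial: State,
    times: ArrayLike,
    rhs: RHSKind | Callable = "crossfeeding",
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the community ODEs on a strictly increasing time grid.

    Uses an adaptive stiff-capable scheme (LSODA by default).  Negative
    densities smaller in magnitude than ``NEGATIVITY_TOLERANCE`` are
    clamped to zero and logged; anything more negative raises
    :class:`SimulationError` carrying the last valid state, as does
    integrator failure.
    """
    initial.check_shapes(params)
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    rhs_fn = _RHS_BY_NAME[rhs] if isinstance(rhs, str) else rhs
    n_r = params.n_resources

    def f(_t, y):
        st = State.__new__(State)  # bypass nonnegativity check mid-step
        object.__setattr__(st, "R", y[:n_r])
        object.__setattr__(st, "S", y[n_r:])
        object.__setattr__(st, "t", _t)
        dR, dS = rhs_fn(st, params)
        return np.concatenate([dR, dS])

    y0 = np.concatenate([initial.R, initial.S])
    sol = solve_ivp(
        f, (t[0], t[-1]), y0, t_eval=t, method=method, rtol=rtol, atol=atol
    )
    y = sol.y.T if sol.y.size else np.empty((0, y0.size))
    if not sol.success:
        last = (
            State(
                R=np.clip(y[-1, :n_r], 0, None),
                S=np.clip(y[-1, n_r:], 0, None),
                t=float(sol.t[-1]),
            )
            if len(sol.t)
            else initial
        )
        raise SimulationError(f"integration failed: {sol.message}", last_state=last)
    worst = y.min(initial=0.0)
    if worst < -NEGATIVITY_TOLERANCE:
        k = int(np.argmin(y.min(axis=1)))
        last = State(
            R=np.clip(y[k - 1 if k else 0, :n_r], 0, None),
            S=np.clip(y[k - 1 if k else 0, n_r:], 0, None),
            t=float(t[k - 1 if k else 0]),
        )
        raise SimulationError(
            f"trajectory went negative ({worst:.3e}) beyond the clamping "
            f"tolerance {NEGATIVITY_TOLERANCE:.0e}",
            last_state=last,
        )
    if worst < 0:
        logger.debug("clamped roundoff negativity of magnitude %.3e to zero", -worst)
        y = np.clip(y, 0.0, None)
    return Trajectory(times=t, R=y[:, :n_r], S=y[:, n_r:])
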