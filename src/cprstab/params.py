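"""Domain types for consumer-producer-resource communities.

A community couples ``N_S`` consumer populations to ``N_R`` abiotic
resources.  Consumers deplete resources according to a nonnegative
consumption matrix ``C`` (rows index resources, columns index consumers)
and may leak metabolites back into the shared pool according to a
production matrix ``P`` of the same shape.  Resources are replenished
from outside the system at rates ``rho`` and optionally leach away at
rates ``eta``; consumers die at rates ``mu`` and convert consumed
resource into biomass with efficiency ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray


class DimensionError(ValueError):
    """Array shapes are mutually inconsistent."""


class RankError(np.linalg.LinAlgError):
    """A matrix required to be invertible is singular or ill-conditioned."""


class DegenerateEquilibriumError(ValueError):
    """An equilibrium resource density vanishes, leaving abundances undefined."""


class SimulationError(RuntimeError):
    """Numerical integration failed; carries the last valid state."""

    def __init__(self, message: str, last_state: "State | None" = None):
        super().__init__(message)
        self.last_state = last_state


class FeasibilityWarning(UserWarning):
    """Inverse rate design produced a nonpositive influx or mortality rate."""


def _as_vector(x: ArrayLike, name: str) -> NDArray[np.float64]:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional, got shape {v.shape}")
    return v


def _as_matrix(x: ArrayLike, name: str) -> NDArray[np.float64]:
    m = np.atleast_2d(np.asarray(x, dtype=float))
    if m.ndim != 2:
        raise DimensionError(f"{name} must be two-dimensional, got shape {m.shape}")
    return m


@dataclass(frozen=True)
class CommunityParameters:
    """Rates defining one consumer-producer-resource community.

    Parameters
    ----------
    C
        Consumption rates, shape ``(N_R, N_S)``; rows are resources,
        columns are consumers.  Entry ``C[i, j]`` is the rate at which
        consumer ``j`` removes resource ``i``, per unit consumer and
        per unit resource.
    P
        Production rates, same shape as ``C`` (per unit consumer per
        time).  Defaults to zero (pure competition).
    rho
        Resource influx, length ``N_R`` (resource per time), positive.
    mu
        Consumer mortality, length ``N_S`` (per time), positive.
    epsilon
        Biomass conversion efficiency, dimensionless, positive.
    eta
        Optional resource leaching rates, length ``N_R`` (per time),
        nonnegative; defaults to zero.
    """

    C: NDArray[np.float64]
    rho: NDArray[np.float64]
    mu: NDArray[np.float64]
    epsilon: float = 1.0
    P: NDArray[np.float64] | None = None
    eta: NDArray[np.float64] | None = None

    def __post_init__(self):
        C = _as_matrix(self.C, "C")
        rho = _as_vector(self.rho, "rho")
        mu = _as_vector(self.mu, "mu")
        P = np.zeros_like(C) if self.P is None else _as_matrix(self.P, "P")
        eta = np.zeros(C.shape[0]) if self.eta is None else _as_vector(self.eta, "eta")
        if P.shape != C.shape:
            raise DimensionError(f"P shape {P.shape} != C shape {C.shape}")
        if rho.shape != (C.shape[0],):
            raise DimensionError(f"rho length {rho.shape[0]} != N_R = {C.shape[0]}")
        if mu.shape != (C.shape[1],):
            raise DimensionError(f"mu length {mu.shape[0]} != N_S = {C.shape[1]}")
        if eta.shape != (C.shape[0],):
            raise DimensionError(f"eta length {eta.shape[0]} != N_R = {C.shape[0]}")
        if np.any(C < 0):
            raise ValueError("C must be entrywise nonnegative")
        if np.any(P < 0):
            raise ValueError("P must be entrywise nonnegative")
        if np.any(rho <= 0):
            raise ValueError("rho must be entrywise positive")
        if np.any(mu <= 0):
            raise ValueError("mu must be entrywise positive")
        if np.any(eta < 0):
            raise ValueError("eta must be entrywise nonnegative")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "epsilon", float(self.epsilon))

    @property
    def n_resources(self) -> int:
        return self.C.shape[0]

    @property
    def n_consumers(self) -> int:
        return self.C.shape[1]

    @property
    def has_production(self) -> bool:
        return bool(np.any(self.P != 0))


@dataclass(frozen=True)
class State:
    """Resource densities ``R`` and consumer abundances ``S`` at time ``t``."""

    R: NDArray[np.float64]
    S: NDArray[np.float64]
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "R", _as_vector(self.R, "R"))
        object.__setattr__(self, "S", _as_vector(self.S, "S"))
        if np.any(self.R < 0) or np.any(self.S < 0):
            raise ValueError("state must be entrywise nonnegative")

    def check_shapes(self, params: CommunityParameters) -> None:
        if self.R.shape[0] != params.n_resources:
            raise DimensionError(
                f"R length {self.R.shape[0]} != N_R = {params.n_resources}"
            )
        if self.S.shape[0] != params.n_consumers:
            raise DimensionError(
                f"S length {self.S.shape[0]} != N_S = {params.n_consumers}"
            )


@dataclass(frozen=True)
class Trajectory:
    """Time course of a community: densities sampled on a strictly
    increasing time grid.  ``R`` has shape ``(T, N_R)`` and ``S`` has
    shape ``(T, N_S)``."""

    times: NDArray[np.float64]
    R: NDArray[np.float64]
    S: NDArray[np.float64]

    def __post_init__(self):
        t = _as_vector(self.times, "times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))

    def __len__(self) -> int:
        return self.times.shape[0]

    def state(self, k: int) -> State:
        return State(R=self.R[k], S=self.S[k], t=float(self.times[k]))

    def states(self) -> Iterator[State]:
        for k in range(len(self)):
            yield self.state(k)


@dataclass(frozen=True)
class SpecialistCommunity:
    """Specialist community ``C = c I`` tuned to a uniform equilibrium.

    Every consumer feeds on exactly one resource at rate ``c`` and the
    influx/mortality rates are chosen so the equilibrium is uniform:
    ``R* = r 1`` and ``S* = s 1``.  ``P`` carries the (otherwise
    unrestricted) mutualistic production rates.
    """

    c: float
    s: float
    r: float
    P: NDArray[np.float64]
    epsilon: float = 1.0

    def __post_init__(self):
        P = _as_matrix(self.P, "P")
        if P.shape[0] != P.shape[1]:
            raise DimensionError("P must be square for a specialist community")
        if np.any(P < 0):
            raise ValueError("P must be entrywise nonnegative")
        for name in ("c", "s", "r", "epsilon"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "P", P)

    @property
    def n(self) -> int:
        return self.P.shape[0]

    @property
    def C(self) -> NDArray[np.float64]:
        return self.c * np.eye(self.n)
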