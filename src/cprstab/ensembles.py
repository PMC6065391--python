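"""Random community ensembles and pooled Jacobian spectra.

An ensemble fixes one consumption matrix (and optionally one production
matrix), then repeatedly draws equilibrium densities from a uniform
distribution, inverse-designs the rates that realise them, and collects
the Jacobian eigenvalues.  Pooled over many draws, the competitive
spectra show the characteristic "dragonfly" shape — imaginary wings of
oscillatory modes plus a dense band of small real eigenvalues — with
every real part negative.  With asymmetric production the pooled
spectrum can cross zero; with symmetric (reciprocal) production subject
to the feasibility constraints it cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.typing import NDArray

from .equilibrium import (
    rates_from_densities,
    specialist_feasibility_constraints,
    specialist_rates,
)
from .params import SpecialistCommunity
from .stability import STABILITY_TOLERANCE, jacobian, rank_condition, specialist_jacobian

logger = logging.getLogger(__name__)

Structure = Literal[
    "specialist_random",
    "generalist_random",
    "specialist_ordered",
    "generalist_ordered",
    "diagonal",
]
Production = Literal["none", "random", "random_symmetric"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Recipe for one ensemble of random communities.

    ``diag_strength`` is each consumer's preference for its favourite
    resource; ``offdiag_scale`` sets the off-diagonal preferences
    (i.i.d. uniform for the ``*_random`` structures, the kernel
    amplitude for the ``*_ordered`` ones, whose preferences decay as a
    Gaussian in circular resource distance with width
    ``kernel_width``).  Equilibrium densities are drawn from
    ``U(density_low, density_high)``; the default band ``(0.1, 1)`` is
    bounded away from zero so that ``diag(R*)`` stays well conditioned.
    """

    N: int = 10
    structure: Structure = "specialist_random"
    diag_strength: float = 1.0
    offdiag_scale: float = 0.2
    kernel_width: float = 1.0
    n_draws: int = 100
    density_low: float = 0.1
    density_high: float = 1.0
    seed: int = 0
    production: Production = "none"
    production_scale: float = 0.1
    epsilon: float = 1.0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if not 0 < self.density_low < self.density_high:
            raise ValueError("need 0 < density_low < density_high")
        for name in ("diag_strength", "offdiag_scale", "kernel_width",
                     "production_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PooledSpectrum:
    """Eigenvalues pooled over every draw of an ensemble."""

    eigenvalues: NDArray[np.complex128]
    n_draws: int
    fraction_unstable: float
    max_real_by_draw: NDArray[np.float64]


def make_consumption_matrix(config: EnsembleConfig) -> NDArray[np.float64]:
    """Draw the ensemble's consumption matrix (deterministic in seed).

    Structures: ``specialist_random`` / ``generalist_random`` put
    ``diag_strength`` on the diagonal and i.i.d. ``U(0, offdiag_scale)``
    off it (weak vs. strong relative to the diagonal);
    ``specialist_ordered`` / ``generalist_ordered`` replace the random
    off-diagonals with a smooth Gaussian kernel in circular resource
    distance from each consumer's favourite resource; ``diagonal`` is
    pure specialism ``diag_strength * I``.  Rank-deficient draws are
    rejected (with a log line) and redrawn.
    """
    rng = np.random.default_rng(config.seed)
    n = config.N
    if config.structure == "diagonal":
        return config.diag_strength * np.eye(n)
    if config.structure in ("specialist_random", "generalist_random"):
        expect_weak = config.structure == "specialist_random"
        if expect_weak and config.offdiag_scale >= config.diag_strength:
            raise ValueError("specialist_random requires offdiag_scale < diag_strength")
        if not expect_weak and config.offdiag_scale <= config.diag_strength:
            raise ValueError("generalist_random requires offdiag_scale > diag_strength")
        for attempt in range(100):
            C = rng.uniform(0.0, config.offdiag_scale, size=(n, n))
            np.fill_diagonal(C, config.diag_strength)
            if rank_condition(C).condition_holds:
                return C
            logger.info("rejected rank-deficient draw %d", attempt)
        raise RuntimeError("could not draw a full-rank consumption matrix")
    if config.structure in ("specialist_ordered", "generalist_ordered"):
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        d = np.minimum(d, n - d)  # circular distance resource i <-> favourite of j
        C = config.offdiag_scale * np.exp(-(d**2) / (2.0 * config.kernel_width**2))
        np.fill_diagonal(C, config.diag_strength)
        if not rank_condition(C).condition_holds:
            raise RuntimeError("ordered kernel matrix is rank deficient")
        return C
    raise ValueError(f"unknown structure {config.structure!r}")


def max_admissible_production_scale(
    P_unit: NDArray[np.float64], c: float, r: float, epsilon: float
) -> float:
    """Largest scalar multiple of ``P_unit`` satisfying both specialist
    feasibility constraints at consumption ``c`` and resource density
    ``r``: mortality needs ``c r eps > colsum``, influx ``c r > rowsum``."""
    col = P_unit.sum(axis=0).max(initial=0.0)
    row = P_unit.sum(axis=1).max(initial=0.0)
    limits = []
    if col > 0:
        limits.append(c * r * epsilon / col)
    if row > 0:
        limits.append(c * r / row)
    return min(limits) if limits else np.inf


def make_production_matrix(
    config: EnsembleConfig,
    c: float | None = None,
    r: float | None = None,
    rescale: bool = True,
    safety: float = 0.95,
) -> NDArray[np.float64]:
    """Draw the ensemble's production matrix (deterministic in seed).

    Entries are i.i.d. ``U(0, production_scale)``; ``random_symmetric``
    symmetrizes as ``(P + P^T)/2`` first.  The matrix is then rescaled
    by a single scalar, if needed, so that the specialist feasibility
    constraints are satisfiable at consumption rate ``c`` and resource
    density ``r`` (defaults: ``diag_strength`` and ``density_high``,
    the best case — individual density draws below that are screened
    per draw); a scalar rescale preserves symmetry and relative
    structure.  With ``rescale=False`` a violating draw raises instead,
    reporting the max admissible scale.
    """
    if config.production == "none":
        return np.zeros((config.N, config.N))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    P = rng.uniform(0.0, config.production_scale, size=(config.N, config.N))
    if config.production == "random_symmetric":
        P = (P + P.T) / 2.0
    elif config.production != "random":
        raise ValueError(f"unknown production mode {config.production!r}")
    c = config.diag_strength if c is None else c
    r = config.density_high if r is None else r
    comm = SpecialistCommunity(c=c, s=1.0, r=r, P=P, epsilon=config.epsilon)
    if specialist_feasibility_constraints(comm).all_ok:
        return P
    factor_limit = max_admissible_production_scale(P, c, r, config.epsilon)
    if not rescale:
        raise ValueError(
            f"production scale {config.production_scale} violates the "
            f"feasibility constraints at c={c}, r={r}; max admissible "
            f"production_scale for this draw is "
            f"{factor_limit * config.production_scale:.4g}"
        )
    factor = safety * factor_limit
    logger.info("rescaled production matrix by %.4g for feasibility", factor)
    return factor * P


def pooled_spectrum(config: EnsembleConfig) -> PooledSpectrum:
    """Pool Jacobian eigenvalues over random equilibrium-density draws.

    The consumption matrix (and any production matrix) is fixed once
    per config; each draw samples densities uniformly, designs the
    rates that make them an equilibrium, and records the spectrum.
    For specialist production runs the uniform scalars ``(r, s)`` are
    drawn instead, rejecting any draw violating the feasibility
    constraints for the fixed production matrix (densities uniform
    subject to the constraints); the production matrix is pre-scaled so
    a feasible region exists.
    """
    C = make_consumption_matrix(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    eigs = []
    max_reals = np.empty(config.n_draws)
    if config.production == "none":
        for k in range(config.n_draws):
            R = rng.uniform(config.density_low, config.density_high, config.N)
            S = rng.uniform(config.density_low, config.density_high, config.N)
            rates_from_densities(C, R, S, config.epsilon)  # validates positivity
            J = jacobian(C, None, R, S, config.epsilon)
            lam = np.linalg.eigvals(J)
            eigs.append(lam)
            max_reals[k] = lam.real.max()
    else:
        if config.structure != "diagonal":
            raise ValueError("production runs require the diagonal structure")
        P = make_production_matrix(config)
        c = config.diag_strength
        for k in range(config.n_draws):
            for _ in range(10_000):
                r = rng.uniform(config.density_low, config.density_high)
                s = rng.uniform(config.density_low, config.density_high)
                comm = SpecialistCommunity(c=c, s=s, r=r, P=P,
                                           epsilon=config.epsilon)
                if specialist_feasibility_constraints(comm).all_ok:
                    break
            else:
                raise RuntimeError(
                    "could not draw feasible densities for the production matrix"
                )
            specialist_rates(comm)
            lam = np.linalg.eigvals(specialist_jacobian(comm))
            eigs.append(lam)
            max_reals[k] = lam.real.max()
    pooled = np.concatenate(eigs)
    frac = float(np.mean(max_reals > STABILITY_TOLERANCE))
    return PooledSpectrum(
        eigenvalues=pooled,
        n_draws=config.n_draws,
        fraction_unstable=frac,
        max_real_by_draw=max_reals,
    )
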