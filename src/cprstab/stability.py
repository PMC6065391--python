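"""Jacobian assembly, eigenvalue spectra, and stability predicates.

Local stability of an equilibrium means every eigenvalue of the
community Jacobian has negative real part.  The central results made
executable here:

* competition only (``P = 0``): every feasible equilibrium is locally
  stable, for any nonnegative consumption matrix of full column rank
  with at least as many resources as consumers;
* specialist crossfeeding (``C = cI``, uniform equilibrium): each
  eigenvalue ``gamma`` of the production matrix maps to a quadratic
  pair of Jacobian eigenvalues, with a sharp per-``gamma`` stability
  condition, a sufficient row-sum bound, and a Gershgorin certificate
  showing that symmetric (reciprocal) production plus feasibility
  already guarantees stability;
* boundary equilibria: stability reduces to the invasion growth rate
  of each absent consumer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .params import DimensionError, SpecialistCommunity

#: half-width of the marginal band around zero for stability verdicts;
#: spectra of large communities pile up real eigenvalues near zero, so
#: a strict sign test on the max real part would be numerically fragile
STABILITY_TOLERANCE = 1e-10


@dataclass(frozen=True)
class Spectrum:
    """Full Jacobian spectrum with a stability verdict.

    ``stable`` is ``max_real < -tol``; ``marginal`` flags a max real
    part inside ``[-tol, +tol]``.  Eigenvalues are sorted by descending
    real part, ties by ascending imaginary part.
    """

    eigenvalues: NDArray[np.complex128]
    max_real: float
    stable: bool
    marginal: bool
    tol: float = STABILITY_TOLERANCE


@dataclass(frozen=True)
class GammaDiagnostics:
    """Specialist-community spectrum organised by production eigenvalues.

    For each eigenvalue ``gamma`` of ``P``, ``lambdas[k]`` holds both
    roots of ``lambda^2 + cs lambda + eps cs (cr - gamma) = 0`` and
    ``stable_flags[k]`` the sharp condition
    ``eps Im(gamma)^2 < cs (cr - Re(gamma))``.
    """

    gammas: NDArray[np.complex128]
    lambdas: NDArray[np.complex128]  # shape (N, 2)
    stable_flags: NDArray[np.bool_]

    @property
    def all_lambdas(self) -> NDArray[np.complex128]:
        return self.lambdas.ravel()

    @property
    def stable(self) -> bool:
        return bool(self.stable_flags.all())


@dataclass(frozen=True)
class RankReport:
    rank: int
    n_resources: int
    n_consumers: int
    condition_holds: bool  # rank(C) == N_S, requires N_S <= N_R


@dataclass(frozen=True)
class ProductionBoundReport:
    """Row-wise sufficient stability bound for specialist crossfeeding:
    ``(sum_{j != i} P_ij)^2 < (cs/eps)(cr - P_ii - cs/(4 eps))``.
    Passing every row guarantees stability; failing does not imply
    instability (the bound is sufficient only)."""

    row_ok: NDArray[np.bool_]
    lhs: NDArray[np.float64]
    rhs: NDArray[np.float64]

    @property
    def all_ok(self) -> bool:
        return bool(self.row_ok.all())


def jacobian(
    C: ArrayLike,
    P: ArrayLike | None,
    R_star: ArrayLike,
    S_star: ArrayLike,
    epsilon: float = 1.0,
    mu: ArrayLike | None = None,
    eta: ArrayLike | None = None,
) -> NDArray[np.float64]:
    """Community Jacobian at ``(R*, S*)``, shape ``(N_R+N_S, N_R+N_S)``.

    Block structure (rows/cols ordered resources then consumers)::

        [ -diag(C S*) - diag(eta)    P - diag(R*) C              ]
        [ eps diag(S*) C^T           diag(eps C^T R* - P^T 1 - mu) ]

    The bottom-right block vanishes at an interior equilibrium; for an
    extirpated consumer ``j`` its ``(j, j)`` entry is the invasion
    growth rate, so the same assembler covers boundary equilibria.
    When ``mu`` is ``None`` the bottom-right block is taken to be zero
    (interior equilibrium assumed).
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n_r, n_s = C.shape
    P = np.zeros_like(C) if P is None else np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape != C.shape:
        raise DimensionError(f"P shape {P.shape} != C shape {C.shape}")
    R_star = np.atleast_1d(np.asarray(R_star, dtype=float))
    S_star = np.atleast_1d(np.asarray(S_star, dtype=float))
    if R_star.shape != (n_r,) or S_star.shape != (n_s,):
        raise DimensionError(
            f"densities ({R_star.shape[0]}, {S_star.shape[0]}) inconsistent "
            f"with C shape {C.shape}"
        )
    eta = np.zeros(n_r) if eta is None else np.atleast_1d(np.asarray(eta, dtype=float))
    if eta.shape != (n_r,):
        raise DimensionError("eta length inconsistent with C")
    J = np.zeros((n_r + n_s, n_r + n_s))
    J[:n_r, :n_r] = -np.diag(C @ S_star + eta)
    J[:n_r, n_r:] = P - R_star[:, None] * C
    J[n_r:, :n_r] = epsilon * S_star[:, None] * C.T
    if mu is not None:
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        if mu.shape != (n_s,):
            raise DimensionError("mu length inconsistent with C")
        growth = epsilon * (C.T @ R_star) - P.sum(axis=0) - mu
        J[n_r:, n_r:] = np.diag(growth)
    return J


def spectrum(J: ArrayLike, tol: float = STABILITY_TOLERANCE) -> Spectrum:
    """Eigenvalues of a real Jacobian with the stability verdict."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    if J.shape[0] != J.shape[1]:
        raise DimensionError(f"Jacobian must be square, got {J.shape}")
    lam = np.linalg.eigvals(J)
    order = np.lexsort((lam.imag, -lam.real))
    lam = lam[order]
    max_real = float(lam.real.max())
    return Spectrum(
        eigenvalues=lam,
        max_real=max_real,
        stable=max_real < -tol,
        marginal=abs(max_real) <= tol,
        tol=tol,
    )


def specialist_jacobian(comm: SpecialistCommunity) -> NDArray[np.float64]:
    """Jacobian of a specialist community at its uniform equilibrium:
    blocks ``[[-cs I, P - cr I], [eps cs I, 0]]``."""
    n = comm.n
    cs, cr = comm.c * comm.s, comm.c * comm.r
    J = np.zeros((2 * n, 2 * n))
    J[:n, :n] = -cs * np.eye(n)
    J[:n, n:] = comm.P - cr * np.eye(n)
    J[n:, :n] = comm.epsilon * cs * np.eye(n)
    return J


def specialist_lambdas(comm: SpecialistCommunity) -> GammaDiagnostics:
    """Map every production eigenvalue ``gamma`` to its pair of
    Jacobian eigenvalues ``lambda = -cs/2 +/- (1/2) sqrt((cs)^2 -
    4 eps cs (cr - gamma))`` (both complex branches).  The union over
    all ``gamma`` is exactly the ``2N`` specialist spectrum.
    """
    gammas = np.linalg.eigvals(comm.P).astype(complex)
    cs, cr, eps = comm.c * comm.s, comm.c * comm.r, comm.epsilon
    disc = np.sqrt(cs**2 - 4.0 * eps * cs * (cr - gammas) + 0j)
    lambdas = np.stack([(-cs + disc) / 2.0, (-cs - disc) / 2.0], axis=1)
    flags = np.array([gamma_condition(g, comm) for g in gammas])
    return GammaDiagnostics(gammas=gammas, lambdas=lambdas, stable_flags=flags)


def gamma_condition(gamma: complex, comm: SpecialistCommunity) -> bool:
    """Sharp per-eigenvalue stability test for specialist crossfeeding:
    both mapped Jacobian roots have negative real part iff
    ``eps Im(gamma)^2 < cs (cr - Re(gamma))``."""
    gamma = complex(gamma)
    cs = comm.c * comm.s
    return bool(
        comm.epsilon * gamma.imag**2 < cs * (comm.c * comm.r - gamma.real)
    )


def sufficient_production_bound(comm: SpecialistCommunity) -> ProductionBoundReport:
    """Row-sum bound sufficient (not necessary) for specialist stability."""
    P = comm.P
    off = P.sum(axis=1) - np.diag(P)
    cs, eps = comm.c * comm.s, comm.epsilon
    lhs = off**2
    rhs = (cs / eps) * (comm.c * comm.r - np.diag(P) - cs / (4.0 * eps))
    return ProductionBoundReport(row_ok=lhs < rhs, lhs=lhs, rhs=rhs)


def gershgorin_symmetric_check(comm: SpecialistCommunity, sym_tol: float = 1e-12) -> bool:
    """Reciprocity certificate: for symmetric ``P`` (all production
    eigenvalues real), Gershgorin's theorem bounds them by the row sums,
    so ``c r > sum_j P_ij`` for every row implies local stability.
    This coincides with the influx feasibility constraint — feasibility
    and reciprocity together imply stability.
    """
    asym = np.abs(comm.P - comm.P.T)
    if asym.max(initial=0.0) > sym_tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            "P must be symmetric: max |P - P^T| entry is "
            f"{asym[i, j]:.3e} at ({i}, {j})"
        )
    return bool(np.all(comm.c * comm.r > comm.P.sum(axis=1)))


def invasion_fitness(
    C: ArrayLike,
    R_star: ArrayLike,
    mu: ArrayLike,
    epsilon: float,
    j: int,
) -> float:
    """Invasion growth rate ``[eps C^T R* - mu]_j`` of consumer ``j``.

    Negative means the boundary equilibrium with ``S*_j = 0`` is
    uninvasible by ``j`` (and stable, given the resident community's
    rank condition); nonnegative means ``j`` can invade or is marginal.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    R_star = np.atleast_1d(np.asarray(R_star, dtype=float))
    if not 0 <= j < C.shape[1]:
        raise IndexError(f"consumer index {j} out of range for N_S = {C.shape[1]}")
    return float(epsilon * (C.T @ R_star)[j] - mu[j])


def rank_condition(C: ArrayLike) -> RankReport:
    """Whether ``rank(C) = N_S`` (hence ``N_S <= N_R``), the condition
    under which feasibility guarantees stability."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    r = int(np.linalg.matrix_rank(C))
    return RankReport(
        rank=r,
        n_resources=C.shape[0],
        n_consumers=C.shape[1],
        condition_holds=r == C.shape[1],
    )


def hermitian_certificate(
    C: ArrayLike,
    R_star: ArrayLike,
    S_star: ArrayLike,
    epsilon: float,
    lam: complex,
) -> bool:
    """Positive-definiteness certificate underlying the competition
    stability theorem.

    For a candidate eigenvalue ``lam`` with ``Re(lam) >= 0``, forms
    ``D1 = eps diag(S*)`` and
    ``D2 = [-diag(C S*) - lam I]^{-1} (-diag(R*))`` and tests whether
    the Hermitian part of ``sqrt(D1) C^T D2 C sqrt(D1)`` is positive
    definite.  It must be whenever ``C`` has full column rank and the
    densities are positive — which rules out any Jacobian eigenvalue in
    the closed right half plane.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    R_star = np.atleast_1d(np.asarray(R_star, dtype=float))
    S_star = np.atleast_1d(np.asarray(S_star, dtype=float))
    lam = complex(lam)
    if lam.real < 0:
        raise ValueError("certificate applies to Re(lam) >= 0 only")
    cs = C @ S_star
    denom = -cs - lam  # diagonal of [-diag(C S*) - lam I]
    if np.any(np.abs(denom) < 1e-14):
        raise ValueError("lam collides with an eigenvalue of -diag(C S*)")
    d2 = -R_star / denom  # diagonal of D2
    sqrt_d1 = np.sqrt(epsilon * S_star)
    M = (sqrt_d1[:, None] * C.T) @ (d2[:, None] * C) * sqrt_d1[None, :]
    H = (M + M.conj().T) / 2.0
    w = np.linalg.eigvalsh(H)
    return bool(w.min() > 1e-12 * max(1.0, abs(w).max()))
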