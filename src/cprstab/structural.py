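"""Structural stability: feasibility-domain volumes and consumer angles.

For a fixed consumption matrix ``C``, the set of mortality vectors
``mu`` producing positive equilibrium resource densities is the convex
cone spanned by the columns of ``C^T``; the set of influx vectors
``rho`` producing positive consumer abundances is the cone spanned by
the columns of ``diag(R*) C``.  The size of either cone — the
structural stability of the community, i.e. its robustness to
environmental shifts in the rates — is measured by

    V = 2 sqrt(det M) / pi^(n/2) * int_{R+^n} exp(-<xi, M xi>) d xi

where ``M`` is the Gram matrix of the normalized cone generators.
Equivalently, ``V`` is twice the fraction of directions on the unit
sphere lying inside the cone; for orthogonal generators at ``n = 3``
this gives ``V = 1/4`` (one octant, doubled by the printed
normalization).  Volumes shrink as consumers become more similar, but
not monotonically in any single pairwise angle: the packaged
three-species example has one pairwise angle increased, the others
fixed, yet a smaller volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

VolumeMethod = Literal["gaussian_mc", "cone_mc", "lhuilier3"]


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric unit-diagonal matrix of cosines between normalized
    cone generators; ``kind`` records which parameter space it bounds."""

    M: NDArray[np.float64]
    kind: Literal["mu", "rho", "generic"] = "generic"

    def __post_init__(self):
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        if M.shape[0] != M.shape[1]:
            raise ValueError("Gram matrix must be square")
        if not np.allclose(M, M.T, atol=1e-12):
            raise ValueError("Gram matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0, atol=1e-10):
            raise ValueError("Gram matrix must have unit diagonal")
        if np.any(np.abs(M) > 1 + 1e-12):
            raise ValueError("Gram entries must lie in [-1, 1]")
        object.__setattr__(self, "M", M)

    @property
    def n(self) -> int:
        return self.M.shape[0]


@dataclass(frozen=True)
class VolumeEstimate:
    """Feasibility-domain volume with Monte Carlo error (0 if closed form)."""

    value: float
    std_error: float
    n_samples: int
    method: VolumeMethod
    seed: int | None = None


def _normalized_columns(A: NDArray[np.float64], what: str) -> NDArray[np.float64]:
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError(f"{what} has a zero column: {np.flatnonzero(norms == 0).tolist()}")
    return A / norms


def pairwise_angles(A: ArrayLike) -> NDArray[np.float64]:
    """Angles (radians) between all pairs of columns of ``A``.

    Symmetric with zero diagonal.  Pass ``C.T`` to get the angles
    between the generators of the mortality cone (the worked
    three-species examples are stated for those columns).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    U = _normalized_columns(A, "matrix")
    cos = np.clip(U.T @ U, -1.0, 1.0)
    theta = np.arccos(cos)
    np.fill_diagonal(theta, 0.0)
    return theta


def gram_matrix(A: ArrayLike, kind: str = "generic") -> GramMatrix:
    """Gram matrix of the normalized columns of ``A``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    U = _normalized_columns(A, "matrix")
    M = U.T @ U
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return GramMatrix(M=M, kind=kind)  # type: ignore[arg-type]


def gram_mu(C: ArrayLike) -> GramMatrix:
    """Gram matrix of the mortality-space cone generators — the
    normalized columns of ``C^T``."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    return gram_matrix(C.T, kind="mu")


def gram_rho(C: ArrayLike, R_star: ArrayLike) -> GramMatrix:
    """Gram matrix of the influx-space cone generators — the normalized
    columns of ``diag(R*) C``.  Depends on the equilibrium resource
    densities, hence (through them) on the chosen mortality rates: the
    influx-space volume is not a property of ``C`` alone.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    R_star = np.atleast_1d(np.asarray(R_star, dtype=float))
    if np.any(R_star <= 0):
        raise ValueError("R_star must be entrywise positive")
    return gram_matrix(R_star[:, None] * C, kind="rho")


def equal_angle_det(a: float, n: int) -> float:
    """Determinant ``(1 - a)^(n-1) (1 + (n-1) a)`` of the n x n Gram
    matrix with all off-diagonal cosines equal to ``a``.

    Monotone decreasing in ``a`` on ``[0, 1)``: uniformly less similar
    consumers always enlarge the feasibility volume.
    """
    if not (-1.0 / (n - 1) < a < 1.0):
        raise ValueError(
            f"a = {a} outside the positive-definite range (-1/{n - 1}, 1)"
        )
    return (1.0 - a) ** (n - 1) * (1.0 + (n - 1) * a)


def _lhuilier_volume(M: NDArray[np.float64]) -> float:
    # spherical triangle with side lengths = pairwise angles; solid
    # angle from L'Huilier's theorem, doubled per the volume convention
    a = math.acos(np.clip(M[1, 2], -1, 1))
    b = math.acos(np.clip(M[0, 2], -1, 1))
    c = math.acos(np.clip(M[0, 1], -1, 1))
    s = (a + b + c) / 2.0
    prod = (
        math.tan(s / 2.0)
        * math.tan((s - a) / 2.0)
        * math.tan((s - b) / 2.0)
        * math.tan((s - c) / 2.0)
    )
    excess = 4.0 * math.atan(math.sqrt(max(prod, 0.0)))
    return 2.0 * excess / (4.0 * math.pi)


def _cholesky_generators(M: NDArray[np.float64]) -> NDArray[np.float64]:
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as err:
        raise ValueError("Gram matrix is not positive definite") from err
    return L.T  # B with B^T B = M; columns are unit vectors realizing M


def feasibility_volume(
    M: GramMatrix | ArrayLike,
    method: VolumeMethod = "gaussian_mc",
    n_samples: int = 1_000_000,
    seed: int | None = None,
) -> VolumeEstimate:
    """Feasibility-domain volume of the cone encoded by a Gram matrix.

    Methods
    -------
    ``gaussian_mc``
        Importance-sampled Monte Carlo of the positive-orthant Gaussian
        integral, with a product-of-half-normals proposal matched to
        ``diag(M)``; the estimate is
        ``2 sqrt(det M) / pi^(n/2)`` times the integral.
    ``cone_mc``
        Geometric oracle: twice the fraction of isotropic random
        directions lying in the cone spanned by unit vectors realizing
        ``M`` (all-nonnegative coordinates in the Cholesky basis).
    ``lhuilier3``
        ``n = 3`` closed form, twice the spherical-triangle solid angle
        (L'Huilier) over ``4 pi``; ``std_error = 0``.
    """
    gram = M if isinstance(M, GramMatrix) else GramMatrix(np.asarray(M, dtype=float))
    Mv = gram.M
    n = gram.n
    if method == "lhuilier3":
        if n != 3:
            raise ValueError("lhuilier3 applies to 3 x 3 Gram matrices only")
        # positive definiteness check via Cholesky
        _cholesky_generators(Mv)
        return VolumeEstimate(
            value=_lhuilier_volume(Mv),
            std_error=0.0,
            n_samples=0,
            method="lhuilier3",
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    B = _cholesky_generators(Mv)
    if method == "cone_mc":
        Z = rng.standard_normal((n_samples, n))
        # coords of each direction in the generator basis
        X = np.linalg.solve(B, Z.T)
        inside = np.all(X >= 0, axis=0)
        p = inside.mean()
        value = 2.0 * p
        se = 2.0 * math.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
        return VolumeEstimate(value=value, std_error=se, n_samples=n_samples,
                              method="cone_mc", seed=seed)
    if method == "gaussian_mc":
        d = np.diag(Mv)  # = 1 for a proper Gram matrix, kept general
        # half-normal proposal q(xi) = prod 2 sqrt(d_i/pi) exp(-d_i xi_i^2)
        xi = np.abs(rng.standard_normal((n_samples, n))) / np.sqrt(2.0 * d)
        log_q = np.sum(
            np.log(2.0) + 0.5 * np.log(d / math.pi) - d * xi**2, axis=1
        )
        log_f = -np.einsum("ki,ij,kj->k", xi, Mv, xi)
        w = np.exp(log_f - log_q)
        integral = w.mean()
        se_integral = w.std(ddof=1) / math.sqrt(n_samples)
        scale = 2.0 * math.sqrt(np.linalg.det(Mv)) / math.pi ** (n / 2.0)
        return VolumeEstimate(
            value=scale * integral,
            std_error=scale * se_integral,
            n_samples=n_samples,
            method="gaussian_mc",
            seed=seed,
        )
    raise ValueError(f"unknown method {method!r}")


def example_matrices() -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """The two 3-species consumption matrices of the worked
    non-monotonicity example, built from exact constants.

    Returns ``(C, C_shifted)`` in the package's storage convention
    (rows = resources, columns = consumers); the mortality-cone
    generators are the columns of each ``C.T``, namely ``(1, 0, 0)``,
    ``(1/sqrt 2, 1/sqrt 2, 0)`` and ``(1/sqrt 3, 1/sqrt 3, 1/sqrt 3)``
    for the first matrix, with the third generator shifted to
    ``(a, b, 1/10)``, ``a = 1/sqrt 3 - sqrt(194/75)/4`` and
    ``b = 1/sqrt 3 + sqrt(194/75)/4``, for the second.  The shift
    increases the (1,3) pairwise angle while leaving the other two
    unchanged — and nevertheless shrinks the feasibility volume.
    """
    s2, s3 = 1.0 / math.sqrt(2.0), 1.0 / math.sqrt(3.0)
    delta = 0.25 * math.sqrt(194.0 / 75.0)
    a, b, c = s3 - delta, s3 + delta, 0.1
    CT = np.array([[1.0, s2, s3], [0.0, s2, s3], [0.0, 0.0, s3]])
    CT_shifted = np.array([[1.0, s2, a], [0.0, s2, b], [0.0, 0.0, c]])
    return CT.T.copy(), CT_shifted.T.copy()
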