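"""Shared draw helpers for randomized tests."""

import numpy as np
from scipy.optimize import linear_sum_assignment

from cprstab import rates_from_densities


def assert_spectra_match(a, b, atol=1e-8):
    """Assert two complex multisets are equal up to atol, pairing the
    elements by optimal assignment (robust to sort-order ties)."""
    a = np.asarray(a, dtype=complex)
    b = np.asarray(b, dtype=complex)
    assert a.shape == b.shape
    D = np.abs(a[:, None] - b[None, :])
    rows, cols = linear_sum_assignment(D)
    worst = D[rows, cols].max()
    assert worst < atol, f"spectra differ by {worst:.3e}"


def draw_consumption_matrix(rng, n_resources, n_consumers, cond_limit=1e6):
    """Entrywise U(0,1) matrix, redrawn until well conditioned (square)
    or of full column rank (rectangular)."""
    while True:
        C = rng.uniform(0.0, 1.0, size=(n_resources, n_consumers))
        if n_resources == n_consumers:
            if np.linalg.cond(C) <= cond_limit:
                return C
        elif np.linalg.matrix_rank(C) == n_consumers:
            return C


def random_competitive_system(rng, n_resources, n_consumers=None):
    """A random feasible competitive community: uniform C, densities
    from U(0.1, 1), rates designed to make them the equilibrium."""
    n_consumers = n_resources if n_consumers is None else n_consumers
    C = draw_consumption_matrix(rng, n_resources, n_consumers)
    R = rng.uniform(0.1, 1.0, n_resources)
    S = rng.uniform(0.1, 1.0, n_consumers)
    rho, mu = rates_from_densities(C, R, S, epsilon=1.0)
    return C, R, S, rho, mu
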