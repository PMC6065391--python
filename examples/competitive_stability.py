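"""Any positive equilibrium of a purely competitive community is stable.

Draws a random 8-species community, picks arbitrary positive target
densities, designs the influx/mortality rates that make them an
equilibrium, and shows that the Jacobian spectrum is strictly in the
left half plane — then confirms by simulating a perturbation.
"""

import numpy as np

from cprstab import (
    CommunityParameters,
    State,
    competitive_equilibrium,
    jacobian,
    rates_from_densities,
    simulate,
    spectrum,
)

rng = np.random.default_rng(42)
n = 8
C = rng.uniform(0.0, 1.0, (n, n))  # arbitrary nonnegative preferences
R_target = rng.uniform(0.1, 1.0, n)
S_target = rng.uniform(0.1, 1.0, n)

rho, mu = rates_from_densities(C, R_target, S_target, epsilon=1.0)
print("designed rates are positive:", bool((rho > 0).all() and (mu > 0).all()))

params = CommunityParameters(C=C, rho=rho, mu=mu)
eq = competitive_equilibrium(params)
print(f"forward solve recovers the targets (residual {eq.residual:.1e}),",
      f"feasible: {eq.feasible}")

spec = spectrum(jacobian(C, None, eq.R_star, eq.S_star, params.epsilon))
print(f"max Re(lambda) = {spec.max_real:.4f}  -> locally stable: {spec.stable}")

traj = simulate(params, State(R=eq.R_star * 1.05, S=eq.S_star * 0.95),
                np.linspace(0, 400, 9), rhs="competition")
dev = np.abs(traj.S - eq.S_star).max(axis=1)
print("max |S - S*| along a 5% perturbation:",
      np.array2string(dev, precision=4))
print("-> the perturbation decays back to the designed equilibrium;")
print("   competition for abiotic resources alone cannot destabilize it.")
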