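"""Structural stability is not a simple function of pairwise similarity.

Computes the feasibility-domain volume V_mu — the size of the set of
mortality-rate vectors that keep all three species coexisting — for the
worked pair of 3-species preference matrices.  Shifting one consumer's
preferences increases its angle to another consumer (they become LESS
similar), yet the coexistence volume shrinks by a factor of five.
"""

import numpy as np

from cprstab import example_matrices, feasibility_volume, gram_mu, pairwise_angles

C, C_shifted = example_matrices()

for label, mat in (("original", C), ("shifted", C_shifted)):
    theta = pairwise_angles(mat.T) / np.pi
    closed = feasibility_volume(gram_mu(mat), method="lhuilier3")
    mc = feasibility_volume(gram_mu(mat), method="gaussian_mc",
                            n_samples=1_000_000, seed=1)
    print(f"{label}: angles/pi = "
          f"({theta[0, 1]:.3f}, {theta[0, 2]:.3f}, {theta[1, 2]:.3f})")
    print(f"  V_mu closed form = {closed.value:.4f}   "
          f"Monte Carlo = {mc.value:.4f} +/- {mc.std_error:.4f}")

print("\nThe (1,3) angle grew from 0.304 pi to 0.444 pi with the other")
print("angles fixed, yet V_mu fell from ~0.0417 to ~0.008: robustness of")
print("coexistence depends on the preference matrix as a whole, not on")
print("pairwise species similarity alone.")
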