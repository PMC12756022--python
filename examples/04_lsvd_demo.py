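"""Fit the learnable SVD layer to a random affinity matrix.

The layer reconstructs A ~ alpha.diag(sigma).alpha^T with row-stochastic
factors from one shared projection. The Frobenius error of the fit is
bounded below by the rank-r truncated SVD (Eckart-Young); the printout
shows how close gradient training gets to that floor.
"""

import numpy as np

from habmil import LSVDLayer, eckart_young_error, fit_to_matrix
from habmil.lsvd import lsvd_project, lsvd_reconstruct

rng = np.random.default_rng(0)
pts = rng.uniform(0, 1, size=(8, 3))
d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
target = np.exp(-d2 / (2 * 0.3**2))  # Gaussian-kernel affinity of 8 points

factors, err = fit_to_matrix(target, rank=4, steps=2000, lr=0.05, seed=0)
floor = eckart_young_error(target, 4)
print(f"fit error      {err:.4f}")
print(f"rank-4 optimum {floor:.4f}  (truncated SVD)")
print(f"ratio          {err / floor:.3f}  (1.0 would be the unreachable floor)")
print("factor rows sum to", factors.alpha_u.sum(axis=1).round(6))
# Every factor row lies on the probability simplex; the reconstruction is
# symmetric because both factors come from the same shared projection.
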