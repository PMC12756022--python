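"""Learnable Singular Value Decomposition (LSVD).

The layer reconstructs an instance-affinity matrix from softmax-constrained
low-rank factors:

    A_hat = alpha_U . diag(sigma) . alpha_V^T,
    alpha_U = alpha_V = softmax_rows(X W_a + b_a),

with one shared affine projection W_a in R^{d x r}, b_a in R^{1 x r} and a
trainable diagonal sigma in R^r (initialized to ones). Because the factor
rows live on the probability simplex the factors are not orthogonal the
way a classical SVD's are; the construction is a learnable low-rank
re-weighting inspired by the SVD, and with a shared projection the
reconstruction is symmetric. Its numerical floor is still the
Eckart-Young bound: no rank-r reconstruction can beat the truncated SVD in
Frobenius error, which the test harness asserts on every fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam, Linear, Module


@dataclass
class LSVDFactors:
    """Numpy snapshot of the factorization at the current parameters."""

    alpha_u: np.ndarray  # (N, r), rows on the simplex
    alpha_v: np.ndarray  # (N, r), equal to alpha_u for the shared projection
    sigma: np.ndarray  # (r,)

    def __post_init__(self):
        for name in ("alpha_u", "alpha_v"):
            a = getattr(self, name)
            if (a < 0).any() or not np.allclose(a.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"{name} rows must be softmax-normalized")

    @property
    def rank(self) -> int:
        return len(self.sigma)


class LSVDLayer(Module):
    def __init__(self, dim: int, rank: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        if rank < 1:
            raise ValueError("rank must be >= 1")
        if rank > dim:
            raise ValueError(f"rank {rank} exceeds feature dimension {dim}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.rank = rank
        self.proj = Linear(dim, rank, rng)  # the shared (W_a, b_a)
        self.sigma = Tensor(np.ones(rank, dtype=np.float64), requires_grad=True)

    def project(self, x: Tensor) -> Tensor:
        """alpha = softmax_rows(X W_a + b_a); requires r <= N."""
        n = x.shape[0]
        if self.rank > n:
            raise ValueError(f"rank {self.rank} exceeds bag size {n}")
        return ad.softmax(self.proj(x), axis=1)

    def reconstruct(self, alpha_u: Tensor, alpha_v: Tensor) -> Tensor:
        """A_hat = alpha_U diag(sigma) alpha_V^T, an (N, N) matrix."""
        return (alpha_u * self.sigma) @ alpha_v.T

    def forward(self, x: Tensor) -> Tensor:
        alpha = self.project(x)
        return self.reconstruct(alpha, alpha)

    def factors(self, x) -> LSVDFactors:
        xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))
        with ad.no_grad():
            alpha = self.project(xt)
        return LSVDFactors(
            alpha_u=alpha.data.copy(),
            alpha_v=alpha.data.copy(),
            sigma=self.sigma.data.copy(),
        )


def lsvd_project(x, layer: LSVDLayer) -> LSVDFactors:
    """Functional alias for :meth:`LSVDLayer.factors`."""
    return layer.factors(x)


def lsvd_reconstruct(factors: LSVDFactors) -> np.ndarray:
    return (factors.alpha_u * factors.sigma) @ factors.alpha_v.T


def eckart_young_error(target: np.ndarray, rank: int) -> float:
    """Frobenius error of the best rank-r approximation (truncated SVD)."""
    s = np.linalg.svd(np.asarray(target, float), compute_uv=False)
    return float(np.sqrt((s[rank:] ** 2).sum()))


def fit_to_matrix(
    target: np.ndarray,
    rank: int,
    steps: int = 2000,
    lr: float = 0.05,
    seed: int = 0,
) -> tuple[LSVDFactors, float]:
    """Gradient-fit the layer to reconstruct ``target`` from X = target.

    A test harness for the layer itself: minimizes the Frobenius
    reconstruction error with Adam and returns the final factors and
    error. Raises if the loss goes non-finite.
    """
    target = np.asarray(target, dtype=np.float64)
    if not np.isfinite(target).all():
        raise ValueError("target must be finite")
    n = target.shape[0]
    if target.shape != (n, n):
        raise ValueError("target must be square (instance-affinity shaped)")
    layer = LSVDLayer(dim=n, rank=rank, rng=np.random.default_rng(seed))
    opt = Adam(layer.parameters(), lr=lr)
    x = Tensor(target)
    t = Tensor(target)
    for _ in range(steps):
        diff = layer(x) - t
        loss = (diff * diff).sum()
        if not np.isfinite(loss.data):
            raise RuntimeError("LSVD fit diverged to a non-finite loss")
        opt.zero_grad()
        loss.backward()
        opt.step()
    final = float(np.sqrt(((target - lsvd_reconstruct(layer.factors(x))) ** 2).sum()))
    return layer.factors(x), final
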