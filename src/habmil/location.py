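"""Positional encodings for instance bags and the CLE fusion stage.

Three encodings of the normalized instance coordinates p = (x, y, z) are
provided:

* ``spe`` — fixed sinusoidal features at dyadic frequencies, concatenated
  to the instance features;
* ``npe`` — a learnable two-layer GELU network
  ``F(p) = a2 . GELU(a1 . p + b1) + b2`` concatenated to the features;
* ``cle`` — the NPE network plus an adaptive importance-weighting
  self-attention ``A = softmax(W H' + b)``, ``O = H' (x) A`` applied to the
  fused features, so the bag re-weights instances by their joint
  appearance-and-location representation.

Both concatenation inputs are standardized per feature across the
instances of the bag first, making the appearance block and the (much
lower-dimensional) location block scale-commensurate.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear, Module

ENCODING_KINDS = ("none", "spe", "npe", "cle")


def sinusoidal_encoding(coords: np.ndarray, n_freq: int = 3) -> np.ndarray:
    """Fixed sin/cos features per axis at frequencies 2**k, k < n_freq.

    Output width is 3 axes x 2 functions x n_freq. Features are periodic
    with period 1 at the base frequency, so coordinate 0 and coordinate 1
    encode identically.
    """
    if n_freq < 1:
        raise ValueError("n_freq must be >= 1")
    coords = np.asarray(coords, dtype=np.float64)
    feats = []
    for k in range(n_freq):
        w = 2.0 * np.pi * (2.0**k)
        feats.append(np.sin(w * coords))
        feats.append(np.cos(w * coords))
    return np.concatenate(feats, axis=1)


class PositionalNetwork(Module):
    """The learnable GELU positional map a2 . GELU(a1 . p + b1) + b2."""

    def __init__(self, d_pos: int = 16, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.lin1 = Linear(3, hidden, rng)
        self.lin2 = Linear(hidden, d_pos, rng)
        self.d_pos = d_pos

    def forward(self, coords) -> Tensor:
        c = coords.data if isinstance(coords, Tensor) else np.asarray(coords)
        if (c < 0).any() or (c > 1).any():
            warnings.warn(
                "coordinates outside [0,1]^3: positional network extrapolates",
                stacklevel=2,
            )
        p = coords if isinstance(coords, Tensor) else Tensor(np.asarray(coords, float))
        return self.lin2(self.lin1(p).gelu())


def encode_positions(coords, params: PositionalNetwork) -> Tensor:
    """Functional alias for :meth:`PositionalNetwork.forward`."""
    return params(coords)


def bag_standardize(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Zero-mean unit-variance per feature column across the bag's instances."""
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))
    mu = x.mean(axis=0, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=0, keepdims=True)
    return centred / (var + eps).sqrt()


def fuse(features, encoded=None) -> Tensor:
    """Eq.-6 fusion: H' = [Norm(F) || Norm(F_hat)] rowwise."""
    f = bag_standardize(features)
    if encoded is None:
        return f
    e = bag_standardize(encoded)
    if f.shape[0] != e.shape[0]:
        raise ValueError(
            f"row mismatch: {f.shape[0]} feature rows vs {e.shape[0]} encoded rows"
        )
    return ad.cat([f, e], axis=1)


class ImportanceWeighting(Module):
    """Adaptive importance weighting A = softmax(W H' + b), O = H' (x) A.

    One scalar score per instance; the softmax runs over the instance axis
    so the weights compare instances within a bag and sum to one.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.score = Linear(dim, 1, rng)

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        if not np.isfinite(h.data).all():
            raise ValueError("non-finite fused features")
        a = ad.softmax(self.score(h), axis=0)  # (N, 1)
        return a, h * a


def importance_weighting(h, params: ImportanceWeighting):
    """Functional alias returning (A, O)."""
    return params(h if isinstance(h, Tensor) else Tensor(np.asarray(h, float)))


class LocationEncoder(Module):
    """Dispatch over the encoding kinds; returns the pooled-stage input."""

    def __init__(self, kind: str, feature_dim: int, d_pos: int = 16,
                 hidden: int = 32, n_freq: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kind not in ENCODING_KINDS:
            raise ValueError(f"unknown positional encoding {kind!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.kind = kind
        self.net: PositionalNetwork | None = None
        self.weighting: ImportanceWeighting | None = None
        self.n_freq = n_freq
        if kind in ("npe", "cle"):
            self.net = PositionalNetwork(d_pos, hidden, rng)
            self.out_dim = feature_dim + d_pos
        elif kind == "spe":
            self.out_dim = feature_dim + 6 * n_freq
        else:
            self.out_dim = feature_dim
        if kind == "cle":
            self.weighting = ImportanceWeighting(self.out_dim, rng)

    def forward(self, features: Tensor, coords: np.ndarray):
        """(N, D) features + (N, 3) coords -> (O, extras)."""
        if self.kind == "none":
            return features, {}
        if self.kind == "spe":
            enc = Tensor(sinusoidal_encoding(coords, self.n_freq))
            return fuse(features, enc), {}
        enc = self.net(coords)
        fused = fuse(features, enc)
        if self.kind == "npe":
            return fused, {}
        a, out = self.weighting(fused)
        return out, {"importance": a}
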