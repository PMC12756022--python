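"""MIL pooling operators: Dynamic Gated Attention and its baselines.

Bag semantics follow the standard MIL assumption: a bag is positive iff at
least one instance is positive (:func:`bag_label_rule`). The pooling
operator ``h`` aggregates the N instance embeddings into one bag embedding
z, which an affine-plus-sigmoid head ``g`` turns into the bag probability.

The DGA pooling combines two per-instance signals:

* a Tanh attention branch, affine -> tanh -> dropout -> affine -> tanh,
  giving a signed activation a_tanh in (-1, 1);
* an LSVD gate: the symmetric low-rank affinity reconstruction A_hat is
  reduced to one scalar per instance by its row mean and squashed by a
  sigmoid, giving a "switch" a_lsvd in (0, 1).

The final weights are a_n = softmax(Linear(a_lsvd . a_tanh)) over the bag
and z = sum_n a_n y_n. Clamping the gate to 1 reduces DGA exactly to the
plain attention baseline, which shares the same scoring path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .lsvd import LSVDLayer
from .nn import Dropout, Linear, Module

POOLING_KINDS = ("max", "mean", "attention", "dga")


def bag_label_rule(instance_labels) -> int:
    """Bag label: 1 iff at least one instance label is 1."""
    labels = list(instance_labels)
    if not labels:
        raise ValueError("empty bag has no label")
    if any(l not in (0, 1) for l in labels):
        raise ValueError("instance labels must be binary")
    return int(sum(labels) > 0)


@dataclass
class AttentionRecord:
    """Per-instance attention signals of one pooled bag."""

    a_tanh: np.ndarray | None  # (N,), in (-1, 1); None for max/mean
    a_lsvd: np.ndarray | None  # (N,), in (0, 1); None unless DGA
    a_final: np.ndarray  # (N,), nonnegative, sums to 1
    z: np.ndarray  # pooled bag embedding

    def __post_init__(self):
        if not np.isclose(self.a_final.sum(), 1.0, atol=1e-6):
            raise ValueError("final attention weights must sum to 1")


@dataclass
class BagPrediction:
    probability: float
    predicted_label: int
    attention: AttentionRecord | None
    subject_id: str


class TanhAttentionBranch(Module):
    """Signed attention scores in (-1, 1) per instance."""

    def __init__(self, dim: int, hidden: int, dropout_rate: float,
                 rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(dim, hidden, rng)
        self.drop = Dropout(dropout_rate, rng)
        self.lin2 = Linear(hidden, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(self.drop(self.lin1(x).tanh())).tanh()  # (N, 1)


class LSVDGate(Module):
    """sigmoid(rowmean(A_hat)): a per-instance switch in (0, 1)."""

    def __init__(self, dim: int, rank: int, rng: np.random.Generator):
        super().__init__()
        self.lsvd = LSVDLayer(dim, rank, rng)

    def forward(self, x: Tensor) -> Tensor:
        a_hat = self.lsvd(x)  # (N, N)
        return a_hat.mean(axis=1, keepdims=True).sigmoid()  # (N, 1)


class DGAPooling(Module):
    """Dynamic Gated Attention pooling.

    ``clamp_gate`` forces a_lsvd to 1, the degenerate case in which DGA
    coincides with the plain attention baseline.
    """

    kind = "dga"

    def __init__(self, dim: int, rng: np.random.Generator, hidden: int = 32,
                 lsvd_rank: int = 4, dropout_rate: float = 0.25):
        super().__init__()
        self.branch = TanhAttentionBranch(dim, hidden, dropout_rate, rng)
        self.gate = LSVDGate(dim, lsvd_rank, rng)
        self.score = Linear(1, 1, rng)
        self.clamp_gate = False

    def forward(self, x: Tensor) -> tuple[Tensor, AttentionRecord]:
        if x.shape[0] < 1:
            raise ValueError("empty bag cannot be pooled")
        a_tanh = self.branch(x)
        if self.clamp_gate:
            a_lsvd = Tensor(np.ones_like(a_tanh.data))
        else:
            a_lsvd = self.gate(x)
        a_final = ad.softmax(self.score(a_lsvd * a_tanh), axis=0)  # (N, 1)
        z = (x * a_final).sum(axis=0)
        record = AttentionRecord(
            a_tanh=a_tanh.data.ravel().copy(),
            a_lsvd=a_lsvd.data.ravel().copy(),
            a_final=a_final.data.ravel().copy(),
            z=z.data.copy(),
        )
        return z, record


class AttentionPooling(Module):
    """Plain attention MIL pooling: the Tanh branch scored and softmaxed."""

    kind = "attention"

    def __init__(self, dim: int, rng: np.random.Generator, hidden: int = 32,
                 dropout_rate: float = 0.25):
        super().__init__()
        self.branch = TanhAttentionBranch(dim, hidden, dropout_rate, rng)
        self.score = Linear(1, 1, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, AttentionRecord]:
        if x.shape[0] < 1:
            raise ValueError("empty bag cannot be pooled")
        a_tanh = self.branch(x)
        a_final = ad.softmax(self.score(a_tanh), axis=0)
        z = (x * a_final).sum(axis=0)
        record = AttentionRecord(
            a_tanh=a_tanh.data.ravel().copy(),
            a_lsvd=None,
            a_final=a_final.data.ravel().copy(),
            z=z.data.copy(),
        )
        return z, record


class MeanPooling(Module):
    kind = "mean"

    def __init__(self, *args, **kwargs):
        super().__init__()

    def forward(self, x: Tensor) -> tuple[Tensor, AttentionRecord]:
        n = x.shape[0]
        if n < 1:
            raise ValueError("empty bag cannot be pooled")
        z = x.mean(axis=0)
        record = AttentionRecord(
            a_tanh=None, a_lsvd=None,
            a_final=np.full(n, 1.0 / n), z=z.data.copy(),
        )
        return z, record


class MaxPooling(Module):
    """Coordinatewise max; reported weights are argmax-instance frequencies."""

    kind = "max"

    def __init__(self, *args, **kwargs):
        super().__init__()

    def forward(self, x: Tensor) -> tuple[Tensor, AttentionRecord]:
        n = x.shape[0]
        if n < 1:
            raise ValueError("empty bag cannot be pooled")
        z = x.max(axis=0)
        counts = np.bincount(x.data.argmax(axis=0), minlength=n).astype(float)
        weights = counts / counts.sum()
        record = AttentionRecord(
            a_tanh=None, a_lsvd=None, a_final=weights, z=z.data.copy()
        )
        return z, record


def make_pooling(kind: str, dim: int, rng: np.random.Generator,
                 hidden: int = 32, lsvd_rank: int = 4,
                 dropout_rate: float = 0.25) -> Module:
    if kind == "dga":
        return DGAPooling(dim, rng, hidden, lsvd_rank, dropout_rate)
    if kind == "attention":
        return AttentionPooling(dim, rng, hidden, dropout_rate)
    if kind == "mean":
        return MeanPooling()
    if kind == "max":
        return MaxPooling()
    raise ValueError(f"unknown pooling kind {kind!r}")


class BagClassifier(Module):
    """The bag-level head g: affine + sigmoid on the pooled embedding."""

    def __init__(self, dim: int, rng: np.random.Generator, threshold: float = 0.5):
        super().__init__()
        self.head = Linear(dim, 1, rng)
        self.threshold = threshold

    def forward(self, z: Tensor) -> Tensor:
        return self.head(z.reshape(1, -1)).sigmoid().reshape(())

    def classify(self, z, attention: AttentionRecord | None = None,
                 subject_id: str = "") -> BagPrediction:
        zt = z if isinstance(z, Tensor) else Tensor(np.asarray(z, float))
        with ad.no_grad():
            p = float(self(zt).data)
        return BagPrediction(
            probability=p,
            predicted_label=int(p >= self.threshold),
            attention=attention,
            subject_id=subject_id,
        )
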