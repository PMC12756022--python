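"""The full weakly supervised bag classifier, with checkpoint I/O.

Pipeline per subject: 3D instance encoder -> positional encoding + fusion
(optional) -> MIL pooling -> bag head. The model is permutation-invariant
in the instances by construction: every stage after the encoder treats
the bag as a set, with positions carried explicitly as coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dga import AttentionRecord, BagClassifier, BagPrediction, make_pooling
from .encoder import EncoderConfig, InstanceEncoder, desk_scale_config
from .location import LocationEncoder
from .nn import Module


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=desk_scale_config)
    pos_encoding: str = "cle"  # none | spe | npe | cle
    pooling: str = "dga"  # max | mean | attention | dga
    d_pos: int = 16
    pos_hidden: int = 32
    n_freq: int = 3
    attn_hidden: int = 32
    attn_dropout: float = 0.25
    lsvd_rank: int = 4
    threshold: float = 0.5

    def with_ablation(self, *, pos_encoding: str | None = None,
                      pooling: str | None = None) -> "ModelConfig":
        """Derived config for ablation cells, all else held fixed."""
        cfg = self
        if pos_encoding is not None:
            cfg = replace(cfg, pos_encoding=pos_encoding)
        if pooling is not None:
            cfg = replace(cfg, pooling=pooling)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"] = asdict(self.encoder)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        enc = d.pop("encoder", {})
        enc = {k: tuple(v) if isinstance(v, list) else v for k, v in enc.items()}
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(encoder=EncoderConfig(**enc), **d)


class HABMIL(Module):
    """Hierarchical attention-based MIL model over multi-modal volumes."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = InstanceEncoder(config.encoder, rng)
        self.location = LocationEncoder(
            config.pos_encoding,
            feature_dim=config.encoder.embed_dim,
            d_pos=config.d_pos,
            hidden=config.pos_hidden,
            n_freq=config.n_freq,
            rng=rng,
        )
        self.pool = make_pooling(
            config.pooling,
            dim=self.location.out_dim,
            rng=rng,
            hidden=config.attn_hidden,
            lsvd_rank=config.lsvd_rank,
            dropout_rate=config.attn_dropout,
        )
        self.head = BagClassifier(self.location.out_dim, rng, config.threshold)
        self._coords_cache: dict[tuple[int, int, int], np.ndarray] = {}

    def _coords(self, spatial_shape) -> np.ndarray:
        key = tuple(spatial_shape)
        if key not in self._coords_cache:
            self._coords_cache[key] = self.encoder.instance_coords(key)
        return self._coords_cache[key]

    def forward(self, volumes: np.ndarray,
                capture: dict | None = None) -> tuple[Tensor, list[AttentionRecord]]:
        """(B, 3, X, Y, Z) float32 -> (probabilities (B,), attention records)."""
        x = Tensor(np.asarray(volumes, dtype=np.float32))
        grid = self.encoder(x, capture=capture)
        coords = self._coords(volumes.shape[2:])
        probs = []
        records = []
        for b in range(volumes.shape[0]):
            feats = self.encoder.flatten_bag(grid, b)  # (N, D) float64
            fused, _extras = self.location(feats, coords)
            z, record = self.pool(fused)
            probs.append(self.head(z).reshape(1))
            records.append(record)
        return ad.cat(probs, axis=0), records

    def predict(self, volumes: np.ndarray,
                subject_ids: list[str] | None = None) -> list[BagPrediction]:
        """Deterministic eval-mode bag predictions."""
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                probs, records = self(volumes)
        finally:
            if was_training:
                self.train()
        out = []
        for b in range(volumes.shape[0]):
            p = float(probs.data[b])
            out.append(
                BagPrediction(
                    probability=p,
                    predicted_label=int(p >= self.config.threshold),
                    attention=records[b],
                    subject_id=(subject_ids[b] if subject_ids else f"bag-{b}"),
                )
            )
        return out


def save_model(model: HABMIL, path: str | Path) -> Path:
    """Checkpoint: parameter arrays + BN running stats + config (.npz)."""
    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    stats = {}
    for j, m in enumerate(model.modules()):
        if hasattr(m, "running_mean"):
            stats[f"bnmean_{j}"] = m.running_mean
            stats[f"bnvar_{j}"] = m.running_var
    np.savez(path, config=json.dumps(model.config.to_dict()), **arrays, **stats)
    return path


def load_model(path: str | Path) -> HABMIL:
    with np.load(Path(path), allow_pickle=False) as z:
        config = ModelConfig.from_dict(json.loads(str(z["config"])))
        model = HABMIL(config, seed=0)
        n = len(model.parameters())
        model.load_state_arrays([z[f"param_{i}"] for i in range(n)])
        for j, m in enumerate(model.modules()):
            if hasattr(m, "running_mean") and f"bnmean_{j}" in z:
                m.running_mean[:] = z[f"bnmean_{j}"]
                m.running_var[:] = z[f"bnvar_{j}"]
    return model.eval()
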