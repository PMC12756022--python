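"""The deep instance generator: a 3D fully-convolutional encoder.

Each stage is convolution -> batch normalization -> ReLU -> 2x max pool ->
dropout; an adaptive max pool then lands on the configured instance grid
(necessary because e.g. a 155-voxel axis is not a power-of-two multiple of
2), followed by a 1x1x1 projection to the embedding dimension D. The
resulting H* x W* x S* x D feature grid is flattened into a bag of
N = H*.W*.S* instances, each with the normalized center coordinate of its
receptive cell — the positional input of the location-encoding stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, pool_bin_edges
from .nn import BatchNorm3d, Conv3d, Dropout, Module


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 3
    stage_channels: tuple[int, ...] = (32, 64, 64)
    kernel: int = 3
    dropout_rate: float = 0.25
    target_instance_grid: tuple[int, int, int] = (2, 2, 2)
    embed_dim: int = 64

    def __post_init__(self):
        if not self.stage_channels:
            raise ValueError("stage_channels must be nonempty")
        if any(t < 1 for t in self.target_instance_grid):
            raise ValueError("target_instance_grid must be >= 1 per axis")

    @property
    def n_instances(self) -> int:
        return int(np.prod(self.target_instance_grid))


def paper_scale_config() -> EncoderConfig:
    """Published-scale configuration: 3x3x3 kernels, 32 first-stage
    channels, 2x2x2x64 output grid for a 240x240x155 input."""
    return EncoderConfig()


def desk_scale_config() -> EncoderConfig:
    """CPU-trainable configuration for 48x48x32 phantom volumes."""
    return EncoderConfig(
        stage_channels=(4, 8, 16),
        dropout_rate=0.1,
        target_instance_grid=(4, 4, 4),
        embed_dim=32,
    )


@dataclass
class InstanceBag:
    """N instance embeddings with their normalized cell-center coordinates."""

    features: np.ndarray  # (N, D)
    coords: np.ndarray  # (N, 3), in [0, 1]^3
    bag_label: int | None
    subject_id: str

    def __post_init__(self):
        if self.features.shape[0] != self.coords.shape[0]:
            raise ValueError("features/coords row mismatch")
        if not np.isfinite(self.features).all():
            raise ValueError("instance features contain NaN/Inf")


class InstanceEncoder(Module):
    """Volume (C, X, Y, Z) -> instance feature grid (D, H*, W*, S*)."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.convs: list[Conv3d] = []
        self.bns: list[BatchNorm3d] = []
        self.dropouts: list[Dropout] = []
        prev = config.in_channels
        for ch in config.stage_channels:
            self.convs.append(Conv3d(prev, ch, config.kernel, rng))
            self.bns.append(BatchNorm3d(ch))
            self.dropouts.append(Dropout(config.dropout_rate, rng))
            prev = ch
        self.proj = Conv3d(prev, config.embed_dim, 1, rng)

    # geometry ------------------------------------------------------------

    def feature_shape_before_adaptive(self, input_shape) -> tuple[int, int, int]:
        shape = list(input_shape)
        for _ in self.convs:
            shape = [s // 2 for s in shape]
        return tuple(shape)

    def check_input_shape(self, input_shape) -> None:
        pre = self.feature_shape_before_adaptive(input_shape)
        tgt = self.config.target_instance_grid
        if any(p < t for p, t in zip(pre, tgt)):
            raise ValueError(
                f"input {tuple(input_shape)} pools to {pre}, below the "
                f"target instance grid {tgt}"
            )

    def instance_cell_edges(self, input_shape):
        """Voxel-space bin edges of each instance's receptive cell.

        The stride of the pooled grid is 2**n_stages; adaptive-pool bins in
        feature space are mapped back through that stride. The last cell on
        each axis absorbs the voxels cropped by odd-sized pooling, so the
        cells tile the input volume without overlap or gaps.
        """
        self.check_input_shape(input_shape)
        stride = 2 ** len(self.convs)
        edges = []
        for axis, size in enumerate(input_shape):
            feat = self.feature_shape_before_adaptive(input_shape)[axis]
            fe = pool_bin_edges(feat, self.config.target_instance_grid[axis])
            ve = fe * stride
            ve[-1] = size  # absorb cropped remainder voxels
            edges.append(ve)
        return tuple(edges)

    def instance_coords(self, input_shape) -> np.ndarray:
        """(N, 3) normalized centers of the receptive cells, C order."""
        e1, e2, e3 = self.instance_cell_edges(input_shape)
        centers = [
            (e[:-1] + e[1:]) / 2.0 / size for e, size in zip((e1, e2, e3), input_shape)
        ]
        g = np.meshgrid(*centers, indexing="ij")
        return np.stack([c.reshape(-1) for c in g], axis=1)

    def instance_cell_boxes(self, input_shape) -> list[tuple[tuple[int, int], ...]]:
        """Per-instance voxel bounding boxes ((x0,x1),(y0,y1),(z0,z1))."""
        e1, e2, e3 = self.instance_cell_edges(input_shape)
        boxes = []
        for i in range(len(e1) - 1):
            for j in range(len(e2) - 1):
                for k in range(len(e3) - 1):
                    boxes.append(
                        (
                            (int(e1[i]), int(e1[i + 1])),
                            (int(e2[j]), int(e2[j + 1])),
                            (int(e3[k]), int(e3[k + 1])),
                        )
                    )
        return boxes

    # forward -------------------------------------------------------------

    def forward(self, x: Tensor, capture: dict | None = None) -> Tensor:
        """(B, C, X, Y, Z) float32 -> (B, D, H*, W*, S*).

        When ``capture`` is given, intermediate stage outputs are stored
        under ``stage{i}`` keys (used by Grad-CAM).
        """
        self.check_input_shape(x.shape[2:])
        h = x
        for i, (conv, bn, drop) in enumerate(zip(self.convs, self.bns, self.dropouts)):
            h = conv(h)
            h = bn(h)
            h = h.relu()
            if capture is not None:
                capture[f"stage{i}"] = h
            h = ad.maxpool3d(h)
            h = drop(h)
        h = ad.adaptive_maxpool3d(h, self.config.target_instance_grid)
        h = self.proj(h)
        if capture is not None:
            capture["projected"] = h
        return h

    def flatten_bag(self, feature_grid: Tensor, sample: int) -> Tensor:
        """One sample of the (B, D, t1, t2, t3) grid -> (N, D) float64."""
        d = self.config.embed_dim
        f = feature_grid[sample]  # (D, t1, t2, t3)
        f = f.reshape(d, -1).transpose()  # (N, D), C order over (x, y, z)
        return f.astype(np.float64)


def extract_features(
    encoder: InstanceEncoder, volume_stack: np.ndarray,
    subject_id: str = "", bag_label: int | None = None,
) -> InstanceBag:
    """Deterministic eval-mode embedding of one standardized volume.

    ``volume_stack`` is the (3, X, Y, Z) channel-first array.
    """
    was_training = encoder.training
    encoder.eval()
    try:
        with ad.no_grad():
            grid = encoder(Tensor(volume_stack[None].astype(np.float32)))
            feats = encoder.flatten_bag(grid, 0).data
    finally:
        if was_training:
            encoder.train()
    coords = encoder.instance_coords(volume_stack.shape[1:])
    return InstanceBag(
        features=feats, coords=coords, bag_label=bag_label, subject_id=subject_id
    )
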