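"""Interpretability: key-patch extraction and 3D Grad-CAM saliency.

Key patches are the receptive cells of the instances with the largest
final attention weights, mapped back to voxel space through the encoder's
pooling geometry. Grad-CAM weights each channel of a chosen encoder stage
by the spatial mean of the bag-logit gradient, rectifies the weighted sum,
and trilinearly upsamples it to the input grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from .model import HABMIL
from .volumes import write_nifti


@dataclass
class KeyPatch:
    instance_index: int
    weight: float
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class SaliencyVolume:
    heat: np.ndarray  # in [0, 1], input shape
    source_layer: str
    subject_id: str


def key_patches(model: HABMIL, volume: np.ndarray, k: int,
                subject_id: str = "") -> list[KeyPatch]:
    """Top-k instances by final attention weight with their voxel boxes.

    Ties are broken by instance index (lower index first); with uniform
    attention the first k cells in C order are returned.
    """
    spatial = volume.shape[1:]
    boxes = model.encoder.instance_cell_boxes(spatial)
    if k > len(boxes):
        raise ValueError(f"k={k} exceeds bag size {len(boxes)}")
    pred = model.predict(volume[None], [subject_id])[0]
    weights = pred.attention.a_final
    order = np.lexsort((np.arange(len(weights)), -weights))
    return [KeyPatch(int(i), float(weights[i]), boxes[int(i)]) for i in order[:k]]


def gradcam3d(model: HABMIL, volume: np.ndarray, target_layer: str | None = None,
              subject_id: str = "") -> SaliencyVolume:
    """Gradient-weighted activation map of an encoder stage for one bag.

    Defaults to the last convolutional stage before flattening (the finest
    grid that still carries class-level gradients). Deterministic in eval
    mode.
    """
    if target_layer is None:
        target_layer = f"stage{len(model.encoder.convs) - 1}"
    model.eval()
    capture: dict[str, Tensor] = {}
    x = volume[None].astype(np.float32)
    probs, _ = model(x, capture=capture)
    if target_layer not in capture:
        raise ValueError(
            f"layer {target_layer!r} has no captured spatial activation; "
            f"available: {sorted(capture)}"
        )
    act = capture[target_layer]
    # backprop the (pre-threshold) bag probability
    probs.backward(np.ones_like(probs.data))
    grad = act.grad
    if grad is None:
        raise RuntimeError("no gradient reached the target layer")
    weights = grad.mean(axis=(2, 3, 4), keepdims=True)  # (1, C, 1, 1, 1)
    cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
    factors = [t / s for t, s in zip(volume.shape[1:], cam.shape)]
    heat = ndimage.zoom(cam.astype(np.float64), factors, order=1,
                        grid_mode=True, mode="nearest")
    heat = heat[: volume.shape[1], : volume.shape[2], : volume.shape[3]]
    pads = [(0, t - s) for t, s in zip(volume.shape[1:], heat.shape)]
    if any(p != (0, 0) for p in pads):
        heat = np.pad(heat, pads)
    lo, hi = heat.min(), heat.max()
    if hi - lo < 1e-12:
        heat = np.zeros_like(heat)  # degenerate (flat) map
    else:
        heat = (heat - lo) / (hi - lo)
    return SaliencyVolume(heat=heat, source_layer=target_layer,
                          subject_id=subject_id)


def saliency_enrichment(saliency: SaliencyVolume, mask: np.ndarray) -> dict:
    """Fraction of saliency mass inside the lesion vs the lesion's volume
    fraction; enrichment > 1 means saliency concentrates on the lesion."""
    total = float(saliency.heat.sum())
    inside = float(saliency.heat[mask.astype(bool)].sum())
    vol_frac = float(mask.astype(bool).mean())
    mass_frac = inside / total if total > 0 else 0.0
    return {
        "mass_in_lesion": mass_frac,
        "lesion_volume_fraction": vol_frac,
        "enrichment": (mass_frac / vol_frac) if vol_frac > 0 else float("nan"),
    }


def render_report(volume: np.ndarray, saliency: SaliencyVolume,
                  patches: list[KeyPatch], out_dir, subject_id: str = "subject",
                  mask: np.ndarray | None = None,
                  modality_index: int = 2) -> list:
    """Write slice-montage panels: original, key-patch overlay, saliency.

    The displayed axial slice is the lesion-center slice when a mask is
    given, otherwise the mid-volume slice. Saliency is overlaid with the
    'hot' colormap; key patches as rectangles. Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.patches as mpatches
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if mask is not None and mask.any():
        z = int(round(ndimage.center_of_mass(mask.astype(float))[2]))
    else:
        z = volume.shape[3] // 2
    base = volume[modality_index, :, :, z].T
    paths = []
    panels = [
        ("original", lambda ax: None),
        ("keypatches", "patches"),
        ("saliency", "heat"),
    ]
    for name, what in panels:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(base, cmap="gray", origin="lower")
        if what == "patches":
            for p in patches:
                (x0, x1), (y0, y1), (z0, z1) = p.box
                if z0 <= z < z1:
                    ax.add_patch(
                        mpatches.Rectangle((x0, y0), x1 - x0, y1 - y0,
                                           fill=False, edgecolor="red", lw=1.5)
                    )
        elif what == "heat":
            ax.imshow(saliency.heat[:, :, z].T, cmap="hot", alpha=0.5,
                      origin="lower")
        ax.set_title(f"{subject_id}: {name} (z={z})", fontsize=9)
        ax.axis("off")
        p = out_dir / f"{subject_id}_{name}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths


def save_saliency(saliency: SaliencyVolume, path) -> None:
    write_nifti(path, saliency.heat.astype(np.float32))
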