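"""Synthetic multi-modal phantom cohorts with known lesion ground truth.

The generator emulates the statistical structure of a skull-stripped,
co-registered multi-parametric brain-MRI cohort at a configurable grid
size: a constant-intensity background with white Gaussian noise, plus
axis-aligned ellipsoidal lesions whose additive contrast differs per
modality. Tumor-like ("positive") lesions carry a multi-modal signature —
hypointense on T1w, hyperintense on T2w and FLAIR — while background-like
distractor lesions are isointense across modalities, so that telling the
classes apart genuinely requires combining modalities rather than spotting
any bright blob.

Two labeling rules are provided:

``presence``
    The bag is positive iff it contains at least one positive lesion (the
    standard MIL assumption). Negative bags may contain distractors.
``octant``
    Every subject carries exactly one positive lesion and the label is 1
    iff its center lies in the designated octant (all coordinates in the
    upper half of their axis). Appearance is then uninformative and
    position is the only signal — the test-bed for positional encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volumes import (
    MANIFEST_COLUMNS,
    MODALITIES,
    MultiModalVolume,
    write_manifest,
    write_nifti,
)

#: additive lesion contrast per (t1w, t2w, flair) for tumor-like lesions,
#: in units of the background standard deviation scale
POSITIVE_CONTRASTS = (-0.4, 0.8, 1.0)
#: isointense-across-modalities signature of background-like distractors
DISTRACTOR_CONTRASTS = (0.8, 0.8, 0.8)
BASE_INTENSITY = 1.0
DEFAULT_NOISE_SD = 0.1
#: per-axis lesion radius as a fraction of the axis length
RADIUS_FRAC = (0.09, 0.16)
DESK_GRID = (48, 48, 32)
PAPER_GRID = (240, 240, 155)


@dataclass(frozen=True)
class Lesion:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    cls: str = "positive"  # "positive" or "background"

    def __post_init__(self):
        if self.cls not in ("positive", "background"):
            raise ValueError(f"unknown lesion class {self.cls!r}")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"lesion radii must be positive, got {self.radii}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one synthetic subject (reproducible from its seed)."""

    subject_id: str
    grid_shape: tuple[int, int, int] = DESK_GRID
    lesions: tuple[Lesion, ...] = ()
    modality_contrasts: tuple[float, float, float] = POSITIVE_CONTRASTS
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if any(g < 8 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 8 per axis, got {self.grid_shape}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for les in self.lesions:
            for c, g in zip(les.center, self.grid_shape):
                if not 0 <= c < g:
                    raise ValueError(
                        f"lesion center {les.center} outside grid {self.grid_shape}"
                    )

    @property
    def bag_label(self) -> int:
        return int(any(l.cls == "positive" for l in self.lesions))


def _ellipsoid(grid_shape, center, radii) -> np.ndarray:
    coords = np.ogrid[tuple(slice(0, g) for g in grid_shape)]
    d = sum(((x - c) / r) ** 2 for x, c, r in zip(coords, center, radii))
    return d <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[MultiModalVolume, np.ndarray, int]:
    """Render a spec into (volume, positive-lesion mask, bag label).

    Deterministic: the same spec (including its seed) always produces
    voxelwise-identical output. The mask marks positive lesions only;
    distractors are visible in the intensities but not in the mask, which
    is the instance-level ground truth for localization tests.
    """
    rng = np.random.default_rng(spec.seed)
    grids = {}
    bumps = []
    for les in spec.lesions:
        contrasts = (
            spec.modality_contrasts if les.cls == "positive" else DISTRACTOR_CONTRASTS
        )
        support = _ellipsoid(spec.grid_shape, les.center, les.radii)
        # Gaussian-smoothed boundary so lesions have soft edges
        bump = gaussian_filter(support.astype(np.float64), sigma=1.0)
        bumps.append((bump, contrasts))
    for mi, m in enumerate(MODALITIES):
        a = BASE_INTENSITY + spec.noise_sd * rng.standard_normal(spec.grid_shape)
        for bump, contrasts in bumps:
            a = a + contrasts[mi] * bump
        grids[m] = a
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for les in spec.lesions:
        if les.cls == "positive":
            mask |= _ellipsoid(spec.grid_shape, les.center, les.radii)
    vol = MultiModalVolume(subject_id=spec.subject_id, **grids)
    return vol, mask, spec.bag_label


# ---------------------------------------------------------------------------
# cohort sampling


def in_designated_octant(center, grid_shape) -> bool:
    """The octant rule: all coordinates in the upper half of their axis."""
    return all(c >= g / 2.0 for c, g in zip(center, grid_shape))


def _sample_radii(rng, grid_shape, radius_frac=RADIUS_FRAC):
    return tuple(float(rng.uniform(*radius_frac) * g) for g in grid_shape)


def _sample_center(rng, grid_shape, radii, octant: bool | None = None,
                   margin: float = 1.0):
    """Uniform lesion center with the lesion fully inside the grid.

    ``octant=True``/``False`` constrains membership of the designated
    octant; ``None`` leaves the position unconstrained. ``margin`` keeps
    the lesion surface at least that many voxels away from every face —
    location studies use a margin of several voxels so that convolution
    boundary effects cannot couple lesion appearance to position.
    """
    for _ in range(1000):
        c = tuple(
            float(rng.uniform(r + margin, g - r - margin))
            for r, g in zip(radii, grid_shape)
        )
        if octant is None or in_designated_octant(c, grid_shape) == octant:
            return c
    raise RuntimeError("could not sample an admissible lesion center")


def sample_cohort_specs(
    n_positive: int,
    n_negative: int,
    grid_shape: tuple[int, int, int] = DESK_GRID,
    label_rule: str = "presence",
    seed: int = 0,
    distractors: bool = True,
    noise_sd: float = DEFAULT_NOISE_SD,
    radius_frac: tuple[float, float] = RADIUS_FRAC,
    margin: float = 1.0,
) -> list[tuple[PhantomSpec, int]]:
    """Draw the per-subject recipes for a cohort (no rendering).

    Returns ``[(spec, label), ...]`` with exactly the requested class
    counts, interleaved positives-first then shuffled deterministically.
    """
    if label_rule not in ("presence", "octant"):
        raise ValueError(f"unknown label rule {label_rule!r}")
    if n_positive < 0 or n_negative < 0:
        raise ValueError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[tuple[PhantomSpec, int]] = []
    labels = [1] * n_positive + [0] * n_negative
    for i, label in enumerate(labels):
        sid = f"sub-{i:04d}"
        sub_seed = int(rng.integers(2**31))
        lesions: list[Lesion] = []
        if label_rule == "presence":
            if label == 1:
                for _ in range(int(rng.integers(1, 3))):
                    radii = _sample_radii(rng, grid_shape, radius_frac)
                    lesions.append(
                        Lesion(_sample_center(rng, grid_shape, radii,
                                              margin=margin), radii, "positive")
                    )
            elif distractors:
                for _ in range(int(rng.integers(1, 3))):
                    radii = _sample_radii(rng, grid_shape, radius_frac)
                    lesions.append(
                        Lesion(_sample_center(rng, grid_shape, radii,
                                              margin=margin), radii, "background")
                    )
        else:  # octant: one positive lesion, label from its position
            radii = _sample_radii(rng, grid_shape, radius_frac)
            center = _sample_center(rng, grid_shape, radii, octant=bool(label),
                                    margin=margin)
            lesions.append(Lesion(center, radii, "positive"))
        spec = PhantomSpec(
            subject_id=sid,
            grid_shape=tuple(grid_shape),
            lesions=tuple(lesions),
            noise_sd=noise_sd,
            seed=sub_seed,
        )
        out.append((spec, label if label_rule == "octant" else spec.bag_label))
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def generate_cohort(
    n_positive: int,
    n_negative: int,
    out_dir: str | Path,
    grid_shape: tuple[int, int, int] = DESK_GRID,
    label_rule: str = "presence",
    seed: int = 0,
    distractors: bool = True,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> pd.DataFrame:
    """Render a cohort to NIfTI files plus a TSV manifest on disk.

    Writing is deterministic byte-for-byte for a fixed seed (gzip mtime is
    pinned), so re-running with identical arguments reproduces identical
    files and checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = sample_cohort_specs(
        n_positive, n_negative, grid_shape, label_rule, seed, distractors, noise_sd
    )
    rows = []
    for spec, label in specs:
        vol, mask, _ = generate_phantom(spec)
        paths = {}
        for m in MODALITIES:
            p = out_dir / f"{spec.subject_id}_{m}.nii.gz"
            write_nifti(p, getattr(vol, m).astype(np.float32))
            paths[m] = str(p)
        mask_path = out_dir / f"{spec.subject_id}_mask.nii.gz"
        write_nifti(mask_path, mask.astype(np.uint8))
        rows.append(
            {
                "subject_id": spec.subject_id,
                **paths,
                "mask": str(mask_path),
                "label": int(label),
            }
        )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest


# ---------------------------------------------------------------------------
# instance-level ground truth


def instance_ground_truth(
    lesion_mask: np.ndarray,
    instance_grid_shape: tuple[int, int, int],
    cell_edges: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-instance binary labels y_i from the voxel-level lesion mask.

    The volume is tiled into the instance grid's receptive blocks (either
    the floor-partition default, or the encoder-supplied ``cell_edges``)
    and an instance is positive iff its block overlaps the positive-lesion
    mask. Returned flat in C order, matching the feature-bag instance
    order, so ``max(y_i)`` equals the presence-rule bag label.
    """
    from .autodiff import pool_bin_edges  # local to avoid a hard cycle

    mask = np.asarray(lesion_mask)
    if mask.ndim != 3:
        raise ValueError("lesion_mask must be 3D")
    if cell_edges is None:
        cell_edges = tuple(
            pool_bin_edges(s, t) for s, t in zip(mask.shape, instance_grid_shape)
        )
    e1, e2, e3 = cell_edges
    if e1[-1] != mask.shape[0] or e2[-1] != mask.shape[1] or e3[-1] != mask.shape[2]:
        raise ValueError(
            f"cell edges {tuple(e[-1] for e in cell_edges)} do not cover mask "
            f"shape {mask.shape}"
        )
    t1, t2, t3 = len(e1) - 1, len(e2) - 1, len(e3) - 1
    if (t1, t2, t3) != tuple(instance_grid_shape):
        raise ValueError("cell_edges inconsistent with instance_grid_shape")
    labels = np.zeros((t1, t2, t3), dtype=np.int8)
    for i in range(t1):
        for j in range(t2):
            for k in range(t3):
                block = mask[e1[i]:e1[i + 1], e2[j]:e2[j + 1], e3[k]:e3[k + 1]]
                labels[i, j, k] = int(block.any())
    return labels.reshape(-1)
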