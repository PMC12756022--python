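"""Multi-modal volume I/O, preprocessing, augmentation and data splits.

Conventions used throughout the package:

* volumes are numpy arrays indexed ``(x, y, z)`` in NIfTI array order,
  0-based voxel indices;
* a subject contributes three co-registered modalities (T1w, T2w, FLAIR)
  of identical shape;
* manifests are tab-separated tables with columns
  ``subject_id, t1w, t2w, flair, mask, label``.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

MODALITIES = ("t1w", "t2w", "flair")
MANIFEST_COLUMNS = ("subject_id", "t1w", "t2w", "flair", "mask", "label")


# ---------------------------------------------------------------------------
# core container


@dataclass
class MultiModalVolume:
    """Three co-registered 3D intensity grids for one subject."""

    subject_id: str
    t1w: np.ndarray
    t2w: np.ndarray
    flair: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shapes = {m: getattr(self, m).shape for m in MODALITIES}
        if len(set(shapes.values())) != 1:
            raise ValueError(
                f"subject {self.subject_id!r}: modality shapes differ: {shapes}"
            )
        for m in MODALITIES:
            a = getattr(self, m)
            if not np.isfinite(a).all():
                raise ValueError(f"subject {self.subject_id!r}: {m} contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1w.shape

    def stacked(self, dtype=np.float32) -> np.ndarray:
        """(3, X, Y, Z) channel-first array in MODALITIES order."""
        return np.stack([getattr(self, m) for m in MODALITIES]).astype(dtype)

    def map_modalities(self, fn) -> "MultiModalVolume":
        return replace(self, **{m: fn(getattr(self, m)) for m in MODALITIES})


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_nifti(path: str | Path, array: np.ndarray,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    """Write a 3D array as NIfTI.

    ``.nii.gz`` output is gzipped with ``mtime=0`` so identical arrays give
    byte-identical files (the seeded-cohort determinism contract).
    """
    path = Path(path)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    if path.name.endswith(".nii.gz"):
        payload = gzip.compress(img.to_bytes(), mtime=0)
        path.write_bytes(payload)
    else:
        nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_volume(manifest_row) -> MultiModalVolume:
    """Load one subject's three modalities from a manifest row.

    The row is any mapping with keys ``subject_id, t1w, t2w, flair``.
    """
    sid = str(manifest_row["subject_id"])
    grids = {}
    spacing = (1.0, 1.0, 1.0)
    for m in MODALITIES:
        p = Path(manifest_row[m])
        if not p.exists():
            raise FileNotFoundError(f"subject {sid!r}: missing {m} file {p}")
        grids[m], spacing = read_nifti(p)
    shapes = {m: g.shape for m, g in grids.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"subject {sid!r}: modality shapes differ: {shapes}")
    return MultiModalVolume(subject_id=sid, voxel_spacing=spacing, **grids)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# preprocessing


def standardize(volume: MultiModalVolume,
                target_shape: tuple[int, int, int]) -> MultiModalVolume:
    """Resample to ``target_shape`` and z-score intensities per modality.

    Trilinear resampling; the z-score statistics are computed over nonzero
    voxels (the usual skull-stripped-MRI convention, where zero is
    background). A constant modality is left centred with a unit
    denominator rather than dividing by zero.
    """
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")

    def one(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=np.float64)
        if a.shape != tuple(target_shape):
            factors = [t / s for t, s in zip(target_shape, a.shape)]
            a = ndimage.zoom(a, factors, order=1, grid_mode=True, mode="nearest")
            # zoom can be off by one voxel for awkward ratios; enforce shape
            a = a[: target_shape[0], : target_shape[1], : target_shape[2]]
            pads = [(0, t - s) for t, s in zip(target_shape, a.shape)]
            if any(p != (0, 0) for p in pads):
                a = np.pad(a, pads)
        support = a != 0
        if not support.any():
            logger.warning("standardize: all-zero modality left unchanged")
            return a
        mu = a[support].mean()
        sd = a[support].std()
        if sd == 0:
            logger.warning("standardize: constant modality, unit denominator used")
            sd = 1.0
        out = a.copy()
        out[support] = (a[support] - mu) / sd
        return out

    return volume.map_modalities(one)


def resample_mask(mask: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour resampling for label masks."""
    if mask.shape == tuple(target_shape):
        return mask
    factors = [t / s for t, s in zip(target_shape, mask.shape)]
    out = ndimage.zoom(mask.astype(np.float32), factors, order=0,
                       grid_mode=True, mode="nearest")
    out = out[: target_shape[0], : target_shape[1], : target_shape[2]]
    pads = [(0, t - s) for t, s in zip(target_shape, out.shape)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads)
    return out > 0.5


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentPolicy:
    """Label-preserving training-time transforms.

    Geometric transforms (flip, affine) use one draw shared by all three
    modalities so co-registration is preserved. ``modality_dropout`` zeroes
    an entire modality with the given probability — the missing-modality
    robustness scheme of training with sequences set to zero.
    """

    flip: bool = False
    affine: bool = False
    intensity_scale: bool = False
    jitter: bool = False
    modality_dropout: float = 0.0
    dropout_candidates: tuple[str, ...] = MODALITIES
    max_rotate_deg: float = 10.0
    max_shift_vox: float = 3.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1

    def is_identity(self) -> bool:
        return not (self.flip or self.affine or self.intensity_scale
                    or self.jitter or self.modality_dropout > 0)


def flip_volume(volume: MultiModalVolume, axes: tuple[int, ...]) -> MultiModalVolume:
    """Mirror all modalities along the given axes (an involution)."""
    if not axes:
        return volume
    return volume.map_modalities(lambda a: np.flip(a, axis=axes).copy())


def _affine_matrix(rng: np.random.Generator, policy: AugmentPolicy):
    theta = np.deg2rad(rng.uniform(-policy.max_rotate_deg, policy.max_rotate_deg))
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    shift = rng.uniform(-policy.max_shift_vox, policy.max_shift_vox, size=3)
    return rot, shift


def augment(volume: MultiModalVolume, policy: AugmentPolicy,
            rng: np.random.Generator) -> MultiModalVolume:
    """Apply the enabled transforms; identity for an empty policy."""
    if policy.is_identity():
        return volume
    out = volume
    if policy.flip:
        axes = tuple(int(a) for a in range(3) if rng.random() < 0.5)
        out = flip_volume(out, axes)
    if policy.affine:
        rot, shift = _affine_matrix(rng, policy)
        center = (np.array(out.shape) - 1) / 2.0
        offset = center - rot @ center + shift

        def warp(a):
            return ndimage.affine_transform(a, rot, offset=offset, order=1,
                                            mode="constant", cval=0.0)

        out = out.map_modalities(warp)
    if policy.intensity_scale:
        s = rng.uniform(*policy.scale_range)
        out = out.map_modalities(lambda a: a * s)
    if policy.jitter:
        # brightness/contrast jitter, the single-channel reading of
        # "color jitter": per-modality affine intensity perturbation
        def jit(a):
            c = 1.0 + rng.uniform(-policy.jitter_contrast, policy.jitter_contrast)
            b = rng.normal(0.0, policy.jitter_brightness)
            return a * c + b

        out = out.map_modalities(jit)
    if policy.modality_dropout > 0 and rng.random() < policy.modality_dropout:
        victim = policy.dropout_candidates[
            int(rng.integers(len(policy.dropout_candidates)))
        ]
        out = replace(out, **{victim: np.zeros_like(getattr(out, victim))})
    return out


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitPlan:
    """Subject-level train/val/test assignment with K folds within train."""

    assignment: dict[str, str]
    folds: dict[str, int]
    k_folds: int
    seed: int

    def subjects(self, partition: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == partition]

    def fold_subjects(self, fold: int) -> tuple[list[str], list[str]]:
        """(train, held-out) subject lists for one CV fold within train."""
        tr = [s for s, f in self.folds.items() if f != fold]
        va = [s for s, f in self.folds.items() if f == fold]
        return tr, va

    def check_disjoint(self) -> None:
        parts = [set(self.subjects(p)) for p in ("train", "val", "test")]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise AssertionError(
                        f"subjects in two partitions: {parts[i] & parts[j]}"
                    )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "k_folds": self.k_folds,
            "assignment": dict(self.assignment),
            "folds": {k: int(v) for k, v in self.folds.items()},
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SplitPlan":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            assignment=payload["assignment"],
            folds=payload["folds"],
            k_folds=payload["k_folds"],
            seed=payload["seed"],
        )


def make_splits(manifest: pd.DataFrame,
                ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                k_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Partition subjects 60/20/20 (default) with K-fold CV inside train.

    The split is at subject level: a subject with several scans in the
    manifest lands with all of them in exactly one partition, so no scan of
    a training subject can leak into test.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    subjects = list(dict.fromkeys(manifest["subject_id"].astype(str)))
    n = len(subjects)
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(n)]
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    train = order[:n_train]
    val = order[n_train : n_train + n_val]
    test = order[n_train + n_val :]
    if k_folds > max(len(train), 1):
        raise ValueError(f"{len(train)} training subjects cannot form {k_folds} folds")
    assignment = {s: "train" for s in train}
    assignment.update({s: "val" for s in val})
    assignment.update({s: "test" for s in test})
    folds: dict[str, int] = {}
    fold_order = [train[i] for i in rng.permutation(len(train))]
    for i, s in enumerate(fold_order):
        folds[s] = i % k_folds
    plan = SplitPlan(assignment=assignment, folds=folds, k_folds=k_folds, seed=seed)
    plan.check_disjoint()
    return plan
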