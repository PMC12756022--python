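"""Training loop, metrics, cross-validation and ablation harnesses.

The empirical MIL risk is the mean of a per-bag loss l(h_f(X_i), Y_i);
binary cross-entropy is used for l since the bag head is a sigmoid.
Optimization is Adam (learning rate 1e-4, weight decay 1e-5 by default,
matching the published protocol; the desk-scale experiment presets use a
larger rate suited to the small phantom networks). Model selection is on
validation AUC; all randomness (shuffling, dropout, augmentation,
initialization) derives from explicit seeds, so a rerun with the same
configuration reproduces the same numbers.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import autodiff as ad
from .autodiff import Tensor
from .model import HABMIL, ModelConfig
from .nn import Adam
from .phantoms import PhantomSpec, generate_phantom
from .volumes import (
    MODALITIES,
    AugmentPolicy,
    MultiModalVolume,
    SplitPlan,
    augment,
    load_volume,
    read_nifti,
    standardize,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Subject:
    """One standardized subject ready for the model."""

    subject_id: str
    volume: np.ndarray  # (3, X, Y, Z) float32, standardized
    label: int
    mask: np.ndarray | None = None  # positive-lesion mask, same grid


def subject_from_volume(vol: MultiModalVolume, label: int,
                        mask: np.ndarray | None = None,
                        target_shape=None) -> Subject:
    target = target_shape if target_shape is not None else vol.shape
    std = standardize(vol, tuple(target))
    return Subject(vol.subject_id, std.stacked(np.float32), int(label), mask)


def cohort_from_specs(specs: list[tuple[PhantomSpec, int]],
                      target_shape=None) -> list[Subject]:
    """Render phantom recipes into in-memory standardized subjects."""
    out = []
    for spec, label in specs:
        vol, mask, _ = generate_phantom(spec)
        out.append(subject_from_volume(vol, label, mask, target_shape))
    return out


def cohort_from_manifest(manifest: pd.DataFrame, target_shape=None) -> list[Subject]:
    out = []
    for _, row in manifest.iterrows():
        vol = load_volume(row)
        mask = None
        if isinstance(row.get("mask"), str) and row["mask"]:
            mask = read_nifti(row["mask"])[0] > 0.5
        out.append(subject_from_volume(vol, int(row["label"]), mask, target_shape))
    return out


def restrict_modalities(stack: np.ndarray, modalities) -> np.ndarray:
    """Zero the channels not in ``modalities`` (missing-sequence protocol)."""
    keep = [m in modalities for m in MODALITIES]
    if all(keep):
        return stack
    out = stack.copy()
    for i, k in enumerate(keep):
        if not k:
            out[i] = 0.0
    return out


# ---------------------------------------------------------------------------
# loss and metrics


def mil_loss(probabilities, labels, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over bags, with epsilon-clamped odds."""
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(
        np.asarray(probabilities, float)
    )
    y = np.asarray(labels, dtype=np.float64)
    if p.shape[0] != y.shape[0]:
        raise ValueError("predictions and labels differ in length")
    pc = p * (1.0 - 2.0 * eps) + eps
    yt = Tensor(y)
    ll = yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()
    return -ll.mean()


@dataclass
class EvalMetrics:
    auc: float
    acc: float
    sensitivity: float
    specificity: float
    roc: list[tuple[float, float]]
    n_test: int
    single_class: bool = False

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "acc": self.acc, "sen": self.sensitivity,
            "spe": self.specificity, "n": self.n_test,
        }


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> EvalMetrics:
    y = np.asarray(labels, int)
    p = np.asarray(probabilities, float)
    pred = (p >= threshold).astype(int)
    single = len(np.unique(y)) < 2
    if single:
        logger.warning("single-class evaluation set: AUC undefined")
        auc, roc = float("nan"), []
    else:
        auc = float(roc_auc_score(y, p))
        fpr, tpr, _ = roc_curve(y, p)
        roc = list(zip(fpr.tolist(), tpr.tolist()))
    acc = float((pred == y).mean())
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    return EvalMetrics(auc, acc, sen, spe, roc, len(y), single)


def predict_probabilities(model: HABMIL, subjects: list[Subject],
                          modalities=MODALITIES, batch_size: int = 8) -> np.ndarray:
    probs = []
    for lo in range(0, len(subjects), batch_size):
        chunk = subjects[lo : lo + batch_size]
        x = np.stack([restrict_modalities(s.volume, modalities) for s in chunk])
        preds = model.predict(x, [s.subject_id for s in chunk])
        probs.extend(pr.probability for pr in preds)
    return np.asarray(probs)


def evaluate(model: HABMIL, subjects: list[Subject],
             modalities=MODALITIES, threshold: float = 0.5) -> EvalMetrics:
    """Deterministic eval-mode metrics on a held-out subject list."""
    probs = predict_probabilities(model, subjects, modalities)
    labels = [s.label for s in subjects]
    return compute_metrics(labels, probs, threshold)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 2
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)
    modalities: tuple[str, ...] = MODALITIES
    class_weighting: bool = False
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def desk_train_config(**overrides) -> TrainConfig:
    """Preset for the small phantom networks: fewer epochs, faster Adam."""
    defaults = dict(epochs=12, batch_size=2, learning_rate=1e-3, weight_decay=1e-5)
    defaults.update(overrides)
    return TrainConfig(**defaults)


@dataclass
class TrainResult:
    model: HABMIL
    log: list[dict]
    best_epoch: int
    best_val_auc: float


def train(model: HABMIL, train_subjects: list[Subject],
          val_subjects: list[Subject], cfg: TrainConfig) -> TrainResult:
    """Seeded end-to-end training with best-checkpoint selection on val AUC."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    weights = {0: 1.0, 1: 1.0}
    if cfg.class_weighting:
        counts = np.bincount([s.label for s in train_subjects], minlength=2)
        total = counts.sum()
        weights = {c: total / (2.0 * max(counts[c], 1)) for c in (0, 1)}
    log: list[dict] = []
    best_state, best_epoch = None, -1
    best_key = (-np.inf, -np.inf)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_subjects))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_subjects[i] for i in order[lo : lo + cfg.batch_size]]
            stacks = []
            for s in batch:
                vol = s.volume
                if not cfg.augment.is_identity():
                    mm = MultiModalVolume(
                        s.subject_id, vol[0].astype(float),
                        vol[1].astype(float), vol[2].astype(float),
                    )
                    mm = augment(mm, cfg.augment, rng)
                    vol = mm.stacked(np.float32)
                stacks.append(restrict_modalities(vol, cfg.modalities))
            x = np.stack(stacks)
            labels = np.array([s.label for s in batch])
            probs, _ = model(x)
            loss = mil_loss(probs, labels)
            if cfg.class_weighting:
                w = np.array([weights[s.label] for s in batch])
                per_bag = _per_bag_bce(probs, labels)
                loss = (per_bag * Tensor(w)).sum() * (1.0 / w.sum())
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: probabilities="
                    f"{probs.data!r}, labels={labels!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_subjects:
            vm = evaluate(model, val_subjects, cfg.modalities, cfg.threshold)
            score = vm.auc if np.isfinite(vm.auc) else -entry["train_loss"]
            entry.update(val_auc=vm.auc, val_acc=vm.acc)
            # ties in val AUC (common on small validation sets) break
            # toward the checkpoint with the lower training loss
            key = (score, -entry["train_loss"])
            if key > best_key:
                best_key, best_epoch = key, epoch
                best_state = model.state_arrays()
        log.append(entry)
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return TrainResult(model, log, best_epoch, best_key[0])


def _per_bag_bce(probs: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    pc = probs * (1.0 - 2.0 * eps) + eps
    yt = Tensor(labels.astype(np.float64))
    return -(yt * pc.log() + (1.0 - yt) * (1.0 - pc).log())


def train_from_manifest(model_config: ModelConfig, train_config: TrainConfig,
                        plan: SplitPlan, manifest: pd.DataFrame,
                        target_shape=None, model_seed: int | None = None):
    """Spec-level entry point: manifest + split plan -> trained model.

    Returns (result, test EvalMetrics).
    """
    subjects = cohort_from_manifest(manifest, target_shape)
    by_id = {s.subject_id: s for s in subjects}
    tr = [by_id[s] for s in plan.subjects("train")]
    va = [by_id[s] for s in plan.subjects("val")]
    te = [by_id[s] for s in plan.subjects("test")]
    model = HABMIL(model_config,
                   seed=model_seed if model_seed is not None else train_config.seed)
    result = train(model, tr, va, train_config)
    metrics = evaluate(result.model, te, train_config.modalities,
                       train_config.threshold) if te else None
    return result, metrics


# ---------------------------------------------------------------------------
# cross-validation and ablation harnesses


def cross_validate(model_config: ModelConfig, train_config: TrainConfig,
                   subjects: list[Subject], k: int = 5,
                   repeats: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated K-fold CV at subject level.

    Returns (per-fold table, aggregate mean/sd table). Fold assignments
    are reshuffled per repeat with a distinct derived seed, so repeats are
    independent but reproducible.
    """
    if k > len(subjects):
        raise ValueError(f"{len(subjects)} subjects cannot form {k} folds")
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng(train_config.seed + 1000 * rep)
        order = rng.permutation(len(subjects))
        folds = [order[i::k] for i in range(k)]
        for fold_idx, held in enumerate(folds):
            held_set = set(held.tolist())
            tr = [subjects[i] for i in range(len(subjects)) if i not in held_set]
            va = [subjects[i] for i in sorted(held_set)]
            cfg = replace(train_config, seed=train_config.seed + 1000 * rep + fold_idx)
            model = HABMIL(model_config, seed=cfg.seed)
            train(model, tr, va, cfg)
            m = evaluate(model, va, cfg.modalities, cfg.threshold)
            rows.append({"repeat": rep, "fold": fold_idx, **m.as_dict()})
    table = pd.DataFrame(rows)
    agg = table[["auc", "acc", "sen", "spe"]].agg(["mean", "std"]).T
    agg.columns = ["mean", "sd"]
    return table, agg.reset_index(names="metric")


@dataclass(frozen=True)
class AblationCell:
    name: str
    model_config: ModelConfig
    modalities: tuple[str, ...] = MODALITIES


def standard_ablation_cells(base: ModelConfig) -> list[AblationCell]:
    """The module-ablation grid: backbone, +CLE, +DGA, full."""
    return [
        AblationCell("backbone", base.with_ablation(pos_encoding="none",
                                                    pooling="attention")),
        AblationCell("cle_only", base.with_ablation(pos_encoding="cle",
                                                    pooling="attention")),
        AblationCell("dga_only", base.with_ablation(pos_encoding="none",
                                                    pooling="dga")),
        AblationCell("full", base.with_ablation(pos_encoding="cle", pooling="dga")),
    ]


def run_ablation(cells: list[AblationCell], subjects: list[Subject],
                 train_config: TrainConfig, seeds: list[int],
                 ratios=(0.6, 0.2, 0.2)) -> pd.DataFrame:
    """Train/evaluate every cell under every seed with paired splits.

    The subject split and all RNG streams depend only on the seed, not the
    cell, so contrasts between cells are paired. Failures in one cell are
    recorded and the run continues.
    """
    rows = []
    ids = pd.DataFrame({"subject_id": [s.subject_id for s in subjects]})
    by_id = {s.subject_id: s for s in subjects}
    for seed in seeds:
        from .volumes import make_splits

        plan = make_splits(ids, ratios=ratios, k_folds=2, seed=seed)
        tr = [by_id[s] for s in plan.subjects("train")]
        va = [by_id[s] for s in plan.subjects("val")]
        te = [by_id[s] for s in plan.subjects("test")]
        for cell in cells:
            cfg = replace(train_config, seed=seed, modalities=cell.modalities)
            try:
                model = HABMIL(cell.model_config, seed=seed)
                train(model, tr, va, cfg)
                m = evaluate(model, te, cell.modalities, cfg.threshold)
                rows.append({"cell": cell.name, "seed": seed, **m.as_dict()})
            except Exception as exc:  # noqa: BLE001 - harness must continue
                logger.error("ablation cell %s seed %d failed: %s",
                             cell.name, seed, exc)
                rows.append({"cell": cell.name, "seed": seed, "error": str(exc)})
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Median/mean/sd per cell, the shape of the published ablation tables."""
    ok = table.dropna(subset=["auc"]) if "auc" in table else table
    return (
        ok.groupby("cell")[["auc", "acc", "sen", "spe"]]
        .agg(["median", "mean", "std"])
        .reset_index()
    )
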