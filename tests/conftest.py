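"""Shared fixtures.

The trained-model fixtures are session-scoped because desk-scale training
runs take tens of seconds each; every test that needs a trained presence
model shares the same five seeded runs.
"""

import numpy as np
import pandas as pd
import pytest

from habmil.encoder import EncoderConfig, desk_scale_config
from habmil.model import HABMIL, ModelConfig
from habmil.phantoms import sample_cohort_specs
from habmil.training import Subject, cohort_from_specs, desk_train_config, evaluate, train
from habmil.volumes import make_splits

PRESENCE_SEEDS = (0, 1, 2, 3, 4)


def tiny_encoder_config() -> EncoderConfig:
    """One-stage encoder for 16^3 smoke volumes."""
    return EncoderConfig(
        stage_channels=(2,), dropout_rate=0.0,
        target_instance_grid=(2, 2, 2), embed_dim=8,
    )


def split_subjects(subjects, seed):
    ids = pd.DataFrame({"subject_id": [s.subject_id for s in subjects]})
    plan = make_splits(ids, seed=seed, k_folds=2)
    by = {s.subject_id: s for s in subjects}
    return (
        [by[s] for s in plan.subjects("train")],
        [by[s] for s in plan.subjects("val")],
        [by[s] for s in plan.subjects("test")],
    )


@pytest.fixture(scope="session")
def presence_cohort():
    """40 positive / 40 negative desk-scale phantoms with distractors."""
    specs = sample_cohort_specs(40, 40, seed=11)
    return cohort_from_specs(specs), specs


@pytest.fixture(scope="session")
def presence_runs(presence_cohort):
    """Five seeded training runs on the presence task.

    Each entry: dict with the trained model, its held-out test subjects
    and their metrics.
    """
    subjects, _specs = presence_cohort
    cfg_base = desk_train_config(epochs=8)
    runs = []
    for seed in PRESENCE_SEEDS:
        tr, va, te = split_subjects(subjects, seed)
        model = HABMIL(ModelConfig(), seed=seed)
        from dataclasses import replace

        result = train(model, tr, va, replace(cfg_base, seed=seed))
        metrics = evaluate(result.model, te)
        runs.append(
            {"seed": seed, "model": result.model, "test": te, "metrics": metrics,
             "result": result}
        )
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
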