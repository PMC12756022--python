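"""Volume I/O, preprocessing, augmentation and split hygiene."""

import numpy as np
import pandas as pd
import pytest

from habmil.volumes import (
    AugmentPolicy,
    MultiModalVolume,
    SplitPlan,
    augment,
    flip_volume,
    load_volume,
    make_splits,
    read_nifti,
    standardize,
    write_nifti,
)


def make_volume(rng, shape=(12, 10, 8), sid="s0"):
    return MultiModalVolume(
        sid,
        rng.normal(1, 0.2, shape),
        rng.normal(1, 0.2, shape),
        rng.normal(1, 0.2, shape),
    )


class TestIO:
    def test_nifti_round_trip(self, tmp_path, rng):
        a = rng.normal(size=(6, 5, 4)).astype(np.float32)
        p = write_nifti(tmp_path / "x.nii.gz", a)
        b, spacing = read_nifti(p)
        np.testing.assert_allclose(a, b, rtol=1e-6)
        assert spacing == (1.0, 1.0, 1.0)

    def test_load_volume_round_trip(self, tmp_path, rng):
        vol = make_volume(rng)
        row = {"subject_id": "s0"}
        for m in ("t1w", "t2w", "flair"):
            row[m] = str(write_nifti(tmp_path / f"{m}.nii.gz",
                                     getattr(vol, m).astype(np.float32)))
        loaded = load_volume(row)
        np.testing.assert_allclose(loaded.t2w, vol.t2w, rtol=1e-5)

    def test_shape_mismatch_names_both_shapes(self, tmp_path, rng):
        row = {"subject_id": "bad"}
        shapes = [(6, 5, 4), (6, 5, 4), (6, 5, 3)]
        for m, sh in zip(("t1w", "t2w", "flair"), shapes):
            row[m] = str(write_nifti(tmp_path / f"{m}.nii.gz",
                                     rng.normal(size=sh).astype(np.float32)))
        with pytest.raises(ValueError, match=r"bad.*\(6, 5, 4\).*\(6, 5, 3\)"):
            load_volume(row)

    def test_missing_file_names_subject(self, tmp_path):
        row = {"subject_id": "s9", "t1w": str(tmp_path / "no.nii.gz"),
               "t2w": "x", "flair": "y"}
        with pytest.raises(FileNotFoundError, match="s9"):
            load_volume(row)

    def test_nan_volume_rejected(self):
        a = np.zeros((8, 8, 8))
        bad = a.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            MultiModalVolume("s", a, bad, a)


class TestStandardize:
    def test_all_zero_target_shaped_volume_unchanged(self):
        z = np.zeros((8, 8, 8))
        vol = MultiModalVolume("s", z, z, z)
        out = standardize(vol, (8, 8, 8))
        assert out.shape == (8, 8, 8)
        assert not out.t1w.any()

    def test_resamples_to_paper_scale_shape(self, rng):
        vol = make_volume(rng, (24, 24, 16))
        out = standardize(vol, (240, 240, 155))
        assert out.shape == (240, 240, 155)

    def test_moments_over_nonzero_support(self, rng):
        vol = make_volume(rng, (16, 16, 16))
        out = standardize(vol, (16, 16, 16))
        for m in ("t1w", "t2w", "flair"):
            a = getattr(out, m)
            nz = a[a != 0]
            assert abs(nz.mean()) < 1e-8
            assert abs(nz.std() - 1) < 1e-8

    def test_degenerate_constant_modality_guarded(self):
        c = np.full((8, 8, 8), 3.0)
        vol = MultiModalVolume("s", c, c, c)
        out = standardize(vol, (8, 8, 8))
        assert np.isfinite(out.t1w).all()


class TestAugment:
    def test_empty_policy_is_identity(self, rng):
        vol = make_volume(rng)
        out = augment(vol, AugmentPolicy(), rng)
        assert out is vol

    def test_flip_is_involution(self, rng):
        vol = make_volume(rng)
        twice = flip_volume(flip_volume(vol, (0, 2)), (0, 2))
        np.testing.assert_array_equal(twice.flair, vol.flair)

    def test_modality_dropout_zeroes_only_the_target(self, rng):
        vol = make_volume(rng)
        policy = AugmentPolicy(modality_dropout=1.0, dropout_candidates=("t1w",))
        out = augment(vol, policy, rng)
        assert not out.t1w.any()
        np.testing.assert_array_equal(out.t2w, vol.t2w)
        np.testing.assert_array_equal(out.flair, vol.flair)

    def test_geometric_transform_shared_across_modalities(self):
        """A marker voxel lands on the same output voxel in all modalities."""
        shape = (16, 16, 16)
        marker = np.zeros(shape)
        marker[4, 11, 7] = 100.0
        vol = MultiModalVolume("s", marker.copy(), marker.copy(), marker.copy())
        policy = AugmentPolicy(flip=True, affine=True)
        out = augment(vol, policy, np.random.default_rng(3))
        pos = [np.unravel_index(np.argmax(getattr(out, m)), shape)
               for m in ("t1w", "t2w", "flair")]
        assert pos[0] == pos[1] == pos[2]
        assert pos[0] != (4, 11, 7)  # transform actually moved it

    def test_seeded_augment_reproducible(self, rng):
        vol = make_volume(rng)
        policy = AugmentPolicy(flip=True, affine=True, jitter=True)
        a = augment(vol, policy, np.random.default_rng(5))
        b = augment(vol, policy, np.random.default_rng(5))
        np.testing.assert_array_equal(a.t1w, b.t1w)


def manifest_of(subjects):
    return pd.DataFrame({"subject_id": subjects})


class TestSplits:
    def test_ten_subjects_split_622(self):
        plan = make_splits(manifest_of([f"s{i}" for i in range(10)]),
                           k_folds=3, seed=0)
        assert len(plan.subjects("train")) == 6
        assert len(plan.subjects("val")) == 2
        assert len(plan.subjects("test")) == 2

    def test_partitions_disjoint_and_exhaustive(self):
        subjects = [f"s{i}" for i in range(23)]
        plan = make_splits(manifest_of(subjects), k_folds=5, seed=4)
        got = sorted(
            plan.subjects("train") + plan.subjects("val") + plan.subjects("test")
        )
        assert got == sorted(subjects)
        plan.check_disjoint()

    def test_duplicate_scans_stay_in_one_partition(self):
        # a manifest with three scans per subject must not split a subject
        rows = [f"s{i}" for i in range(12) for _ in range(3)]
        plan = make_splits(manifest_of(rows), k_folds=2, seed=1)
        assert len(plan.assignment) == 12
        plan.check_disjoint()

    def test_same_seed_identical_different_seed_differs(self):
        m = manifest_of([f"s{i}" for i in range(30)])
        p1 = make_splits(m, k_folds=5, seed=8)
        p2 = make_splits(m, k_folds=5, seed=8)
        p3 = make_splits(m, k_folds=5, seed=9)
        assert p1.assignment == p2.assignment and p1.folds == p2.folds
        assert p1.assignment != p3.assignment

    def test_folds_cover_train_only(self):
        plan = make_splits(manifest_of([f"s{i}" for i in range(20)]),
                           k_folds=4, seed=2)
        assert sorted(plan.folds) == sorted(plan.subjects("train"))
        assert set(plan.folds.values()) == {0, 1, 2, 3}
        tr, va = plan.fold_subjects(0)
        assert not set(tr) & set(va)

    def test_too_few_subjects_for_folds(self):
        with pytest.raises(ValueError, match="folds"):
            make_splits(manifest_of(["a", "b", "c"]), k_folds=5, seed=0)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            make_splits(manifest_of(["a", "b"]), ratios=(0.5, 0.2, 0.2),
                        k_folds=1, seed=0)

    def test_yaml_round_trip(self, tmp_path):
        plan = make_splits(manifest_of([f"s{i}" for i in range(10)]),
                           k_folds=2, seed=3)
        p = plan.to_yaml(tmp_path / "plan.yaml")
        back = SplitPlan.from_yaml(p)
        assert back == plan
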