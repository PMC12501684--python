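"""Fold splitting, augmentation and the optimization loop."""

import numpy as np
import pytest

from asldenoise.metrics import LossParams
from asldenoise.model import Denoiser3D, micro_config
from asldenoise.training import (PlateauSchedule, TrainSchedule, augment,
                                 kfold_split, micro_schedule, train_denoiser)


class TestKFold:
    def test_paper_scale_fold_sizes(self):
        ids = [f"sub-{i:03d}" for i in range(152)]
        split = kfold_split(ids, k=4, seed=0)
        for f in range(4):
            assert len(split.test_ids(f)) == 38
            assert len(split.trainval_ids(f)) == 114
            assert len(split.val_ids(f)) == 11   # floor(0.10 * 114)
            assert len(split.train_ids(f)) == 103

    def test_folds_partition_all_subjects(self):
        ids = list("abcdefghijk")
        split = kfold_split(ids, k=3, seed=1)
        seen = []
        for f in range(3):
            fold = split.test_ids(f)
            assert len(fold) in (3, 4)
            seen += fold
        assert sorted(seen) == sorted(ids)

    def test_leave_one_out_degenerate(self):
        ids = list("abc")
        split = kfold_split(ids, k=3, seed=0)
        assert all(len(split.test_ids(f)) == 1 for f in range(3))

    def test_reproducible_and_k_validation(self):
        ids = list("abcdefgh")
        s1 = kfold_split(ids, k=4, seed=7)
        s2 = kfold_split(ids, k=4, seed=7)
        assert s1.fold_assignments == s2.fold_assignments
        with pytest.raises(ValueError):
            kfold_split(ids, k=9)


class TestAugment:
    def test_deterministic_mode_is_8x(self, rng):
        vols = rng.normal(size=(3, 8, 8, 4))
        out = augment(vols, "deterministic")
        assert out.shape == (24, 8, 8, 4)
        # all 8 variants of a volume are distinct for generic data
        assert len({a.tobytes() for a in out[:8]}) == 8

    def test_paper_scale_augmented_count(self):
        """114 scans x (32 time points + M0) x 8 symmetries = 30 096."""
        n_scans, n_vols = 114, 33
        ops = 8
        assert n_scans * n_vols * ops == 30096

    def test_double_flip_is_identity(self, rng):
        vols = rng.normal(size=(1, 8, 8, 4))
        once = augment(vols, "deterministic")
        flipped = once[1]  # pure y-flip variant
        again = augment(flipped[None], "deterministic")[1]
        np.testing.assert_array_equal(again, vols[0])

    def test_full_mode_zero_ranges_reduce_to_deterministic(self, rng):
        vols = rng.normal(size=(2, 8, 8, 4))
        det = augment(vols, "deterministic")
        full = augment(vols, "full", seed=0, shift_range=0.0, rot_range=0.0)
        np.testing.assert_allclose(full, det, atol=1e-12)

    def test_same_seed_keeps_pairs_aligned(self, rng):
        # a coordinate phantom: transforming x and y with one seed keeps
        # their voxelwise relationship intact
        base = rng.normal(size=(2, 8, 8, 4))
        pair = 2.0 * base
        a = augment(base, "full", seed=3, shift_range=2.0)
        b = augment(pair, "full", seed=3, shift_range=2.0)
        # linear interpolation commutes with scaling, so identical
        # transform streams keep the pair relation exactly
        np.testing.assert_allclose(b, 2.0 * a, atol=1e-9)

    def test_nonsquare_inplane_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(rng.normal(size=(1, 8, 6, 4)), "deterministic")


class TestPlateauSchedule:
    def test_halves_after_patience_without_improvement(self):
        sched = PlateauSchedule(0.002, drop=0.5, patience=15, lr_min=1e-5)
        sched.update(1.0)  # first value becomes best
        for _ in range(14):
            assert sched.update(1.0) == 0.002
        assert sched.update(1.0) == 0.001

    def test_no_drop_while_improving(self):
        sched = PlateauSchedule(0.002, drop=0.5, patience=3, lr_min=1e-5)
        for loss in np.linspace(1.0, 0.1, 20):
            assert sched.update(loss) == 0.002

    def test_floor_at_lr_min(self):
        sched = PlateauSchedule(0.002, drop=0.5, patience=1, lr_min=1e-3)
        sched.update(1.0)
        for _ in range(10):
            lr = sched.update(1.0)
        assert lr == 1e-3


class TestTrainDenoiser:
    def test_validation_loss_improves(self, cohort):
        from asldenoise.experiments import build_training_pairs, split_cohort
        train, val, _ = split_cohort(cohort, seed=5)
        X, Y = build_training_pairs(train, n_av=4, max_samples=32)
        Xv, Yv = build_training_pairs(val, n_av=4)
        model = Denoiser3D(micro_config(seed=0))
        model, hist = train_denoiser(
            model, (X, Y), (Xv, Yv),
            micro_schedule(seed=0, max_epochs=12, early_stop_after=12))
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        assert len(hist["train_loss"]) == len(hist["val_loss"])
        assert hist["best_val_loss"] == min(hist["val_loss"])

    def test_empty_training_set_rejected(self, rng):
        model = Denoiser3D(micro_config())
        empty = (np.empty((0, 16, 16, 8)), np.empty((0, 16, 16, 8)))
        val = (rng.normal(size=(2, 16, 16, 8)),
               rng.normal(size=(2, 16, 16, 8)))
        with pytest.raises(ValueError):
            train_denoiser(model, empty, val, micro_schedule())

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TrainSchedule(lr_init=1e-6, lr_min=1e-3)
        with pytest.raises(ValueError):
            TrainSchedule(patience=0)
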