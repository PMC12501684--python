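"""Metric identities, the combined loss, dichotomization and the
stage-wise improvement decomposition."""

import numpy as np
import pytest

from asldenoise.averaging import AveragingPlan
from asldenoise.metrics import (PSNR_CAP_DB, LossParams, combined_loss,
                                dichotomize_snr, nmae, nme, psnr,
                                score_volume, ssim3d, stepwise_improvement)
from asldenoise.model import IdentityDenoiser


class TestSSIM:
    def test_identity_is_one(self, rng):
        x = rng.normal(size=(12, 12, 8))
        assert ssim3d(x, x) == pytest.approx(1.0)

    def test_equal_constants_are_one(self):
        x = np.full((10, 10, 8), 2.5)
        assert ssim3d(x, x.copy()) == pytest.approx(1.0)

    def test_monotone_decrease_with_noise(self, rng):
        base = rng.normal(size=(16, 16, 8))
        vals = []
        for std in (0.5, 1.0, 2.0):
            noisy = base + np.random.default_rng(1).normal(
                0, std, base.shape)
            vals.append(ssim3d(noisy, base))
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            ssim3d(rng.normal(size=(8, 8, 8)), rng.normal(size=(8, 8, 4)))


class TestPSNR:
    def test_identity_capped(self, rng):
        x = rng.normal(size=(8, 8, 4))
        assert psnr(x, x.copy(), data_range=1.0) == PSNR_CAP_DB

    def test_closed_forms(self):
        a = np.zeros((8, 8, 4))
        b = np.full((8, 8, 4), 1.0)
        assert psnr(a, b, data_range=1.0) == pytest.approx(0.0)
        b = np.full((8, 8, 4), 0.1)
        assert psnr(a, b, data_range=1.0) == pytest.approx(20.0)

    def test_nonpositive_range_rejected(self, rng):
        x = rng.normal(size=(4, 4, 4))
        with pytest.raises(ValueError):
            psnr(x, x, data_range=0.0)


class TestNMAEandNME:
    def test_closed_forms(self, rng):
        ref = rng.uniform(0.5, 1.5, size=(8, 8, 4))
        mask = np.ones(ref.shape, bool)
        assert nmae(ref, ref, mask) == 0.0
        assert nmae(1.1 * ref, ref, mask) == pytest.approx(0.1)
        c = 0.05 * ref.mean()
        assert nmae(ref + c, ref, mask) == pytest.approx(0.05)
        assert nme(1.1 * ref, ref, mask) == pytest.approx(0.1)
        assert nme(0.9 * ref, ref, mask) == pytest.approx(-0.1)

    def test_nme_bounded_by_nmae(self, rng):
        ref = rng.uniform(0.5, 1.5, size=(8, 8, 4))
        for seed in range(5):
            x = ref + np.random.default_rng(seed).normal(0, 0.3, ref.shape)
            assert abs(nme(x, ref, None)) <= nmae(x, ref, None) + 1e-12

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            nmae(np.ones((4, 4, 4)), np.zeros((4, 4, 4)), None)

    def test_range_normalizer_flag(self, rng):
        ref = rng.uniform(0.5, 1.5, size=(8, 8, 4))
        x = ref + 0.1
        expected = 0.1 / (ref.max() - ref.min())
        assert nmae(x, ref, None, normalizer="range") == \
            pytest.approx(expected)
        with pytest.raises(ValueError):
            nmae(x, ref, None, normalizer="median")


class TestCombinedLoss:
    def test_zero_at_identity(self, rng):
        x = rng.normal(size=(8, 8, 8))
        assert combined_loss(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_w_zero_is_mse(self, rng):
        a = rng.normal(size=(8, 8, 8))
        b = rng.normal(size=(8, 8, 8))
        assert combined_loss(a, b, LossParams(w=0.0)) == \
            pytest.approx(np.mean((a - b) ** 2))

    def test_w_one_is_one_minus_ssim(self, rng):
        b = rng.normal(size=(12, 12, 8))
        a = b + rng.normal(0, 0.3, b.shape)
        assert combined_loss(a, b, LossParams(w=1.0)) == \
            pytest.approx(1.0 - ssim3d(a, b))

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            LossParams(w=1.5)


class TestDichotomize:
    def test_separated_blobs_fully_recovered(self, rng):
        lo = np.column_stack([rng.normal(0.3, 0.01, 10),
                              rng.normal(1.0, 0.01, 10)])
        hi = np.column_stack([rng.normal(0.9, 0.01, 10),
                              rng.normal(0.2, 0.01, 10)])
        labels = dichotomize_snr(np.vstack([lo, hi]), seed=0)
        assert list(labels[:10]) == ["low"] * 10
        assert list(labels[10:]) == ["high"] * 10

    def test_invariant_to_affine_feature_rescaling(self, rng):
        feats = np.column_stack([rng.uniform(0.2, 0.9, 12),
                                 rng.uniform(0.1, 1.2, 12)])
        l1 = dichotomize_snr(feats, seed=0)
        scaled = feats * np.array([100.0, 0.01]) + np.array([5.0, -3.0])
        l2 = dichotomize_snr(scaled, seed=0)
        assert list(l1) == list(l2)

    def test_degenerate_features_rejected(self):
        feats = np.tile([[0.5, 0.5]], (6, 1))
        with pytest.raises(ValueError):
            dichotomize_snr(feats)

    def test_generator_regimes_recovered(self, cohort):
        from asldenoise.metrics import snr_features
        feats = snr_features(cohort)
        labels = dichotomize_snr(feats, seed=0)
        truth = np.array([s.regime for s in cohort])
        assert np.mean(labels == truth) >= 0.95


class TestStepwise:
    def test_identity_model_and_trivial_plan(self, scan):
        plan = AveragingPlan(n_av_pre=1, n_av_post=1,
                             n_timepoints=scan.n_timepoints)
        out = stepwise_improvement(scan, plan, IdentityDenoiser(),
                                   scan.gt(1.0))
        for metric, d in out["deltas"].items():
            assert d["pre"] == pytest.approx(0.0, abs=1e-12)
            assert d["dl"] == pytest.approx(0.0, abs=1e-12)
            assert d["post"] == pytest.approx(0.0, abs=1e-12)

    def test_deltas_telescope(self, scan, trained_model):
        plan = AveragingPlan(n_av_pre=4, n_av_post=8,
                             n_timepoints=scan.n_timepoints)
        out = stepwise_improvement(scan, plan, trained_model, scan.gt(1.0))
        for metric, d in out["deltas"].items():
            assert d["pre"] + d["dl"] + d["post"] == \
                pytest.approx(d["total"], abs=1e-9)

    def test_pre_averaging_improves_quality(self, scan):
        plan = AveragingPlan(n_av_pre=8, n_av_post=4,
                             n_timepoints=scan.n_timepoints)
        out = stepwise_improvement(scan, plan, IdentityDenoiser(),
                                   scan.gt(1.0))
        assert out["deltas"]["ssim"]["pre"] > 0
        assert out["deltas"]["nmae"]["pre"] < 0


def test_score_volume_records_all_fields():
    rng = np.random.default_rng(3)
    ref = rng.uniform(0.5, 1.0, size=(8, 8, 8))
    x = ref + rng.normal(0, 0.1, ref.shape)
    rec = score_volume(x, ref, None, stage="input", subject_id="sub-001")
    assert rec.stage == "input"
    assert rec.nmae >= abs(rec.nme)
    assert -1.0 <= rec.ssim <= 1.0
    assert np.isfinite(rec.psnr)
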