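"""Generator properties: determinism, geometry, noise statistics, artifacts."""

import numpy as np
import pytest

from asldenoise import (AcquisitionParams, inject_artifacts, make_cohort,
                        make_phantom, simulate_series)
from asldenoise.metrics import nmae, ssim3d
from asldenoise.synthetic import REGIME_SIGMA, SimulationConfig


class TestPhantom:
    def test_determinism(self):
        a = make_phantom((16, 16, 8), seed=3)
        b = make_phantom((16, 16, 8), seed=3)
        assert np.array_equal(a.cbf_map, b.cbf_map)
        assert np.array_equal(a.tissue_map, b.tissue_map)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)

    def test_rejects_small_dimensions(self):
        with pytest.raises(ValueError):
            make_phantom((4, 16, 8), seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_mask_fraction_within_band(self, seed):
        p = make_phantom((64, 64, 32), seed=seed)
        assert 0.30 <= p.brain_mask.mean() <= 0.60

    @pytest.mark.parametrize("seed", range(10))
    def test_cortical_shell_contrast(self, seed):
        p = make_phantom((16, 16, 8), seed=seed)
        shell, core = p.region_masks()
        assert p.cbf_map[shell].mean() / p.cbf_map[core].mean() >= 2.0

    def test_field_support_and_ordering(self, phantom):
        m = phantom.brain_mask
        assert np.all(phantom.tissue_map[m] >= phantom.cbf_map[m])
        assert np.all(phantom.cbf_map >= 0)
        # sparse vessels inside the brain
        assert phantom.vessel_mask.sum() <= 0.01 * m.sum() + 1
        assert not np.any(phantom.vessel_mask & ~m)
        # fields vanish away from the (enlarged) brain support
        assert phantom.cbf_map[0, 0, 0] == 0.0
        assert phantom.tissue_map[0, 0, 0] == 0.0


class TestSimulateSeries:
    def test_zero_noise_reproduces_perfusion(self, phantom):
        params = AcquisitionParams(n_timepoints=4, noise_sigma=0.0,
                                   temporal_jitter=0.0, seed=0)
        scan = simulate_series(phantom, params)
        for t in range(4):
            assert np.allclose(scan.series[t], phantom.cbf_map)

    def test_determinism(self, phantom):
        p = AcquisitionParams(seed=11)
        s1 = simulate_series(phantom, p)
        s2 = simulate_series(phantom, p)
        assert np.array_equal(s1.series, s2.series)
        assert np.array_equal(s1.m0, s2.m0)

    def test_noise_std_recovered(self, phantom):
        sigma = 0.3
        params = AcquisitionParams(n_timepoints=32, noise_sigma=sigma,
                                   temporal_jitter=0.0, seed=2)
        scan = simulate_series(phantom, params)
        resid = scan.series - scan.series.mean(axis=0)
        # unbiased correction for subtracting the temporal mean
        emp = resid.std() * np.sqrt(32 / 31)
        assert abs(emp - sigma) / sigma < 0.05

    def test_temporal_mean_error_shrinks_with_noise(self, phantom):
        def in_mask_err(sigma):
            params = AcquisitionParams(n_timepoints=32, noise_sigma=sigma,
                                       temporal_jitter=0.0, seed=4)
            scan = simulate_series(phantom, params)
            return nmae(scan.series.mean(axis=0), phantom.cbf_map,
                        phantom.brain_mask)
        assert in_mask_err(0.2) < in_mask_err(0.4)

    @pytest.mark.parametrize("seed", range(10))
    def test_regimes_separate_on_ssim(self, seed):
        p = make_phantom((16, 16, 8), seed=seed)
        gt = np.where(p.brain_mask, p.cbf_map, 0.0)
        vals = {}
        for regime in ("low", "high"):
            scan = simulate_series(
                p, AcquisitionParams(snr_regime=regime, seed=100 + seed))
            vals[regime] = ssim3d(
                np.where(p.brain_mask, scan.series[0], 0.0), gt)
        assert vals["low"] < vals["high"]

    def test_averaging_noise_reduction_sqrt_n(self, phantom):
        sigma = REGIME_SIGMA["high"]
        params = AcquisitionParams(n_timepoints=8, noise_sigma=sigma,
                                   temporal_jitter=0.0, seed=6)
        scan = simulate_series(phantom, params)
        resid = scan.series.mean(axis=0) - phantom.cbf_map
        expected = sigma / np.sqrt(8)
        assert abs(resid.std() - expected) / expected < 0.10


class TestArtifacts:
    def test_zero_rate_is_identity(self, phantom):
        scan = simulate_series(phantom, AcquisitionParams(
            artifact_rate=0.0, seed=1))
        out = inject_artifacts(scan, "transient_motion", seed=2)
        assert np.array_equal(out.series, scan.series)

    def test_transient_motion_flags_match_changes(self, phantom):
        scan = simulate_series(phantom, AcquisitionParams(
            artifact_rate=0.3, seed=1))
        out = inject_artifacts(scan, "transient_motion", seed=2)
        flagged = set(out.meta["artifacts"]["timepoints"])
        assert 0 < len(flagged) <= int(0.2 * scan.n_timepoints) + 1
        for t in range(scan.n_timepoints):
            changed = not np.array_equal(out.series[t], scan.series[t])
            assert changed == (t in flagged)

    def test_intravascular_shifts_mean_not_std(self, phantom):
        scan = simulate_series(phantom, AcquisitionParams(seed=1))
        out = inject_artifacts(scan, "intravascular", seed=2)
        v = phantom.vessel_mask
        np.testing.assert_allclose(out.series[:, v].std(axis=0),
                                   scan.series[:, v].std(axis=0))
        assert np.all(out.series[:, v].mean(axis=0)
                      > scan.series[:, v].mean(axis=0))

    def test_unknown_kind_rejected(self, scan):
        with pytest.raises(ValueError):
            inject_artifacts(scan, "gamma-ray", seed=0)


class TestStructuredComponents:
    def test_alternating_residual_cancels_in_pairs(self, phantom):
        params = AcquisitionParams(n_timepoints=8, noise_sigma=0.0,
                                   temporal_jitter=0.0,
                                   alt_residual_amp=0.2, seed=3)
        scan = simulate_series(phantom, params)
        pair_mean = scan.series[:2].mean(axis=0)
        assert np.allclose(pair_mean, phantom.cbf_map, atol=1e-12)
        # a single time point carries the residual
        assert not np.allclose(scan.series[0], phantom.cbf_map)

    def test_drift_is_linear_and_zero_mean(self, phantom):
        params = AcquisitionParams(n_timepoints=8, noise_sigma=0.0,
                                   temporal_jitter=0.0,
                                   temporal_drift=0.4, seed=3)
        scan = simulate_series(phantom, params)
        assert np.allclose(scan.series.mean(axis=0), phantom.cbf_map,
                           atol=1e-12)
        m = phantom.brain_mask
        scale = [scan.series[t][m].mean() / phantom.cbf_map[m].mean()
                 for t in range(8)]
        diffs = np.diff(scale)
        assert np.allclose(diffs, diffs[0], atol=1e-9)


def test_cohort_mixes_regimes_deterministically():
    c1 = make_cohort(n_subjects=6, n_low=2, shape=(16, 16, 8),
                     n_timepoints=4, seed=9)
    c2 = make_cohort(n_subjects=6, n_low=2, shape=(16, 16, 8),
                     n_timepoints=4, seed=9)
    assert [s.regime for s in c1] == ["low"] * 2 + ["high"] * 4
    for a, b in zip(c1, c2):
        assert np.array_equal(a.series, b.series)


def test_simulation_config_yaml_roundtrip(tmp_path):
    path = tmp_path / "sim.yaml"
    path.write_text(
        "shape: [16, 16, 8]\nn_subjects: 3\nn_low: 1\nn_timepoints: 4\n"
        "seed: 2\n")
    cfg = SimulationConfig.from_yaml(path)
    scans = cfg.cohort()
    assert len(scans) == 3
    assert scans[0].series.shape == (4, 16, 16, 8)
    with pytest.raises(KeyError):
        (tmp_path / "bad.yaml").write_text("nonsense_key: 1\n")
        SimulationConfig.from_yaml(tmp_path / "bad.yaml")
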