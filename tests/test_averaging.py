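"""Averaging algebra: grouping rules, partition properties, linearity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asldenoise.averaging import (AveragingPlan, DivisibilityError,
                                  count_instances, group_indices,
                                  post_average, pre_average)


class TestGroupIndices:
    def test_nav_one_is_identity_partition(self):
        assert group_indices(4, 1, "windowed") == [[0], [1], [2], [3]]

    def test_windowed_and_interleaved_enumeration(self):
        assert group_indices(8, 2, "windowed") == \
            [[0, 1], [2, 3], [4, 5], [6, 7]]
        assert group_indices(8, 2, "interleaved") == \
            [[0, 4], [1, 5], [2, 6], [3, 7]]

    @given(st.sampled_from([(8, 2), (8, 4), (32, 16), (12, 3), (32, 1)]),
           st.sampled_from(["windowed", "interleaved"]))
    @settings(deadline=None)
    def test_groups_partition_the_index_set(self, nt_nav, scheme):
        n_t, n_av = nt_nav
        groups = group_indices(n_t, n_av, scheme)
        flat = [i for g in groups for i in g]
        assert len(groups) == n_t // n_av
        assert all(len(g) == n_av for g in groups)
        assert sorted(flat) == list(range(n_t))

    def test_nondivisible_rejected(self):
        with pytest.raises(DivisibilityError):
            group_indices(10, 4, "windowed")


class TestPreAverage:
    def test_full_average_equals_temporal_mean(self, rng):
        series = rng.normal(size=(8, 4, 4, 2))
        plan = AveragingPlan(n_av_pre=8, n_timepoints=8)
        out = pre_average(series, plan)
        assert out.shape == (1, 4, 4, 2)
        np.testing.assert_allclose(out[0], series.mean(axis=0))

    def test_nav_one_is_identity(self, rng):
        series = rng.normal(size=(4, 4, 4, 2))
        out = pre_average(series, AveragingPlan(n_av_pre=1, n_timepoints=4))
        np.testing.assert_array_equal(out, series)

    @pytest.mark.parametrize("scheme", ["windowed", "interleaved"])
    def test_constant_series_unchanged(self, scheme, rng):
        vol = rng.normal(size=(4, 4, 2))
        series = np.repeat(vol[None], 8, axis=0)
        out = pre_average(series, AveragingPlan(scheme=scheme, n_av_pre=4,
                                                n_timepoints=8))
        for v in out:
            np.testing.assert_allclose(v, vol)

    def test_shape_mismatch_rejected(self, rng):
        series = rng.normal(size=(6, 4, 4, 2))
        with pytest.raises(ValueError):
            pre_average(series, AveragingPlan(n_av_pre=2, n_timepoints=8))


class TestPostAverage:
    def test_instance_counts(self, rng):
        vols = rng.normal(size=(16, 4, 4, 2))
        assert post_average(vols, 4).shape[0] == 4
        assert post_average(vols, 16).shape[0] == 1
        np.testing.assert_allclose(post_average(vols, 16)[0],
                                   vols.mean(axis=0))
        np.testing.assert_array_equal(post_average(vols, 1), vols)

    def test_divisibility_error(self, rng):
        with pytest.raises(DivisibilityError):
            post_average(rng.normal(size=(6, 2, 2, 2)), 4)


class TestCountInstances:
    @pytest.mark.parametrize("args,expected", [
        ((32, 2, 4), 4),      # the canonical full-use example
        ((32, 1, 32), 1),
        ((32, 16, 2), 1),
        ((32, 1, 1), 32),
    ])
    def test_counts(self, args, expected):
        assert count_instances(*args) == expected

    def test_broken_chain_rejected(self):
        with pytest.raises(DivisibilityError):
            count_instances(32, 3, 4)
        with pytest.raises(DivisibilityError):
            count_instances(32, 16, 4)


class TestChainProperties:
    @pytest.mark.parametrize("scheme", ["windowed", "interleaved"])
    @pytest.mark.parametrize("n_av_pre", [1, 2, 8, 16])
    def test_full_chain_equals_grand_mean(self, scheme, n_av_pre, rng):
        series = rng.normal(size=(16, 4, 4, 2))
        plan = AveragingPlan(scheme=scheme, n_av_pre=n_av_pre,
                             n_av_post=16 // n_av_pre, n_timepoints=16)
        out = post_average(pre_average(series, plan), plan.n_av_post)
        assert out.shape[0] == 1
        np.testing.assert_allclose(out[0], series.mean(axis=0), atol=1e-12)

    def test_schemes_share_the_grand_mean(self, rng):
        series = rng.normal(size=(16, 4, 4, 2))
        outs = []
        for scheme in ("windowed", "interleaved"):
            plan = AveragingPlan(scheme=scheme, n_av_pre=4, n_av_post=4,
                                 n_timepoints=16)
            outs.append(post_average(pre_average(series, plan), 4)[0])
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-12)

    def test_noise_reduction_follows_sqrt_n(self, rng):
        n, n_av = 32, 8
        series = rng.normal(0.0, 1.0, size=(n, 16, 16, 8))
        plan = AveragingPlan(n_av_pre=n_av, n_timepoints=n)
        out = pre_average(series, plan)
        expected = 1.0 / np.sqrt(n_av)
        assert abs(out.std() - expected) / expected < 0.10
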