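"""PREP robust-statistics criteria: channel and epoch flagging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegqc import QCConfig, epoch, prep_bad_channels, prep_bad_epochs
from eegqc.preprocessing import EpochArray
from eegqc.prep_qc import robust_std, robust_zscore

from _reference import ref_prep_bad_channels, ref_prep_bad_epochs
from conftest import toy_recording


class TestRobustStd:
    def test_constant_zero(self):
        assert robust_std(np.full(8, 3.0)) == 0.0

    def test_0123(self):
        # linear-interpolation quartiles: Q1 = 0.75, Q3 = 2.25
        assert robust_std(np.array([0.0, 1, 2, 3])) == pytest.approx(
            1.5 * 0.7413, abs=1e-12)

    def test_gaussian_consistency(self):
        rng = np.random.default_rng(0)
        assert 0.99 <= robust_std(rng.standard_normal(10 ** 6)) <= 1.01

    def test_too_short(self):
        with pytest.raises(ValueError):
            robust_std(np.array([1.0, 2, 3]))


class TestRobustZscore:
    def test_constant_all_zero(self):
        np.testing.assert_array_equal(robust_zscore(np.full(6, 2.0)),
                                      np.zeros(6))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40))
    def test_median_zero(self, values):
        z = robust_zscore(np.array(values))
        scale = max(1.0, np.abs(z[np.isfinite(z)]).max()) if np.isfinite(z).any() else 1.0
        assert abs(np.median(z)) < 1e-9 * scale

    def test_outlier_more_extreme_than_plain_z(self):
        from eegqc.faster_qc import zscore
        rng = np.random.default_rng(1)
        v = rng.standard_normal(16)
        v[7] = 50.0
        assert abs(robust_zscore(v)[7]) > abs(zscore(v)[7])


class TestPrepBadChannels:
    def test_flat_channel_flagged(self, clean_filtered, cfg):
        data = clean_filtered.data.copy()
        data[2] = 0.0
        res = prep_bad_channels(clean_filtered.copy_with(data=data), cfg)
        assert res.per_criterion["flat"][2]
        assert res.bad[2]

    def test_nan_channel_flagged(self, clean_filtered, cfg):
        data = clean_filtered.data.copy()
        data[9, 1000:1100] = np.nan
        res = prep_bad_channels(clean_filtered.copy_with(data=data), cfg)
        assert res.per_criterion["flat"][9]

    def test_partially_flat_channel_flagged(self, clean_filtered, cfg):
        # flat in ~5% of 2 s windows, alive otherwise
        data = clean_filtered.data.copy()
        win = int(2.0 * clean_filtered.fs)
        data[4, :3 * win] = 0.0
        res = prep_bad_channels(clean_filtered.copy_with(data=data), cfg)
        assert res.per_criterion["flat"][4]

    def test_uncorrelated_channel_flagged(self, clean_filtered, cfg):
        rng = np.random.default_rng(3)
        data = clean_filtered.data.copy()
        data[6] = rng.standard_normal(data.shape[1]) * data[6].std()
        res = prep_bad_channels(clean_filtered.copy_with(data=data), cfg)
        assert res.per_criterion["correlation"][6]

    def test_clean_data_unflagged(self, clean_filtered, cfg):
        res = prep_bad_channels(clean_filtered, cfg)
        assert res.bad.sum() == 0

    def test_dead_channel_does_not_mask_others(self, clean_filtered, cfg):
        # a flat channel must not absorb the robust-Z budget of a loud one
        data = clean_filtered.data.copy()
        data[0] = 0.0
        data[5] *= 30
        res = prep_bad_channels(clean_filtered.copy_with(data=data), cfg)
        assert res.per_criterion["flat"][0]
        assert res.per_criterion["amplitude"][5]

    def test_gain_invariance_except_flat(self, clean_filtered, cfg):
        data = clean_filtered.data.copy()
        data[5] *= 30  # amplitude-criterion target
        rec = clean_filtered.copy_with(data=data)
        a = prep_bad_channels(rec, cfg)
        b = prep_bad_channels(rec.copy_with(data=rec.data * 250.0), cfg)
        for k in ("amplitude", "correlation", "noisiness"):
            np.testing.assert_array_equal(a.per_criterion[k], b.per_criterion[k])

    def test_flat_criterion_is_absolute_scale(self, clean_filtered, cfg):
        # shrinking everything below the absolute threshold flags all
        tiny = clean_filtered.copy_with(data=clean_filtered.data * 1e-18)
        res = prep_bad_channels(tiny, cfg)
        assert res.per_criterion["flat"].all()


class TestPrepBadEpochs:
    def test_identical_epochs_unflagged(self, cfg):
        one = np.random.default_rng(0).standard_normal((1, 4, 512))
        ep = EpochArray(data=np.tile(one, (10, 1, 1)), fs=256.0, epoch_len_s=2.0)
        assert prep_bad_epochs(ep, cfg).bad.sum() == 0

    def test_single_channel_burst_flagged(self, clean_epochs, cfg):
        data = clean_epochs.data.copy()
        data[17, 3] *= 20  # burst confined to one channel, one epoch
        ep = EpochArray(data=data, fs=clean_epochs.fs, epoch_len_s=2.0)
        res = prep_bad_epochs(ep, cfg)
        assert res.bad[17]
        assert res.per_criterion["scale"][17]

    def test_clean_false_flag_rate(self, clean_epochs, cfg):
        assert prep_bad_epochs(clean_epochs, cfg).bad.mean() <= 0.05

    def test_monotonicity_in_artifact_size(self, clean_epochs, cfg):
        flagged_at = []
        for gain in (5.0, 20.0, 80.0):
            data = clean_epochs.data.copy()
            data[8, 1] *= gain
            ep = EpochArray(data=data, fs=clean_epochs.fs, epoch_len_s=2.0)
            flagged_at.append(bool(prep_bad_epochs(ep, cfg).bad[8]))
        # once flagged, larger artifacts stay flagged
        assert flagged_at == sorted(flagged_at)
        assert flagged_at[-1]

    def test_gain_invariance(self, cfg):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((12, 4, 512))
        data[5, 2] *= 15
        a = prep_bad_epochs(EpochArray(data=data, fs=256.0, epoch_len_s=2.0), cfg)
        b = prep_bad_epochs(EpochArray(data=data * 77, fs=256.0, epoch_len_s=2.0), cfg)
        np.testing.assert_array_equal(a.bad, b.bad)

    def test_too_few_epochs(self, cfg):
        ep = EpochArray(data=np.zeros((3, 4, 512)), fs=256.0, epoch_len_s=2.0)
        with pytest.raises(ValueError):
            prep_bad_epochs(ep, cfg)

    def test_components_exposed(self, clean_epochs, cfg):
        res = prep_bad_epochs(clean_epochs, cfg)
        assert set(res.per_criterion) == {"location", "scale"}
        assert "max_robust_z" in res.scores


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_epoch_flags_match_reference(self, seed, cfg):
        rec = toy_recording(seed + 50)
        ep = epoch(rec, cfg.epoch_len_s)
        got = prep_bad_epochs(ep, cfg).bad
        np.testing.assert_array_equal(
            got, ref_prep_bad_epochs(ep.data, cfg.prep_robust_z))

    @pytest.mark.parametrize("seed", range(6))
    def test_channel_flags_match_reference(self, seed, cfg):
        rec = toy_recording(seed + 200)
        got = prep_bad_channels(rec, cfg).bad
        np.testing.assert_array_equal(got, ref_prep_bad_channels(rec, cfg))
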