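"""Synthetic-EEG generator: determinism, fidelity, detector recovery."""

from dataclasses import replace

import numpy as np
import pytest

from eegqc import (
    epoch,
    faster_bad_channels,
    faster_bad_epochs,
    highpass,
    peak_alpha_frequency,
    prep_bad_channels,
    prep_bad_epochs,
    welch_psd,
)
from eegqc.simulate import (
    AlphaSpec,
    ArtifactSpec,
    LineNoiseSpec,
    SyntheticSpec,
    fractional_gaussian_noise,
    generate_cohort,
    generate_recording,
)

SHORT = SyntheticSpec(duration_s=30.0, seed=0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a, _ = generate_recording(SHORT)
        b, _ = generate_recording(SHORT)
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a, _ = generate_recording(SHORT)
        b, _ = generate_recording(replace(SHORT, seed=1))
        assert not np.array_equal(a.data, b.data)


class TestValidation:
    def test_all_errors_listed(self):
        spec = replace(SHORT, n_channels=0, fs=-1.0)
        with pytest.raises(ValueError) as err:
            generate_recording(spec)
        assert "n_channels" in str(err.value) and "fs" in str(err.value)

    def test_alpha_peak_outside_band(self):
        spec = replace(SHORT, alpha=AlphaSpec(peak_hz=20.0))
        with pytest.raises(ValueError, match="alpha peak"):
            generate_recording(spec)

    def test_artifact_out_of_range(self):
        spec = replace(SHORT, artifacts=(ArtifactSpec("flat_channel",
                                                      channel=99),))
        with pytest.raises(ValueError, match="out of range"):
            generate_recording(spec)

    def test_unknown_artifact_kind(self):
        with pytest.raises(ValueError, match="kind"):
            ArtifactSpec("explosion")


class TestCleanSignalProperties:
    def test_windowed_correlation_above_prep_floor(self):
        rec, _ = generate_recording(SHORT)
        win = 512
        k = rec.n_samples // win
        for w in range(k):
            seg = rec.data[:, w * win:(w + 1) * win]
            c = np.corrcoef(seg)
            np.fill_diagonal(c, np.nan)
            best = np.nanmax(np.abs(c), axis=1)
            assert (best >= 0.4).all()

    def test_background_spectral_slope(self):
        # log-log PSD slope of the alpha-free background matches the
        # requested 1/f exponent within +/-0.2
        spec = replace(SHORT, duration_s=120.0, seed=3,
                       alpha=AlphaSpec(amplitude_uv=0.0),
                       noise_floor_frac=0.02)
        rec, _ = generate_recording(spec)
        psd = welch_psd(rec, window_s=4.0)
        sel = (psd.freqs >= 1.0) & (psd.freqs <= 30.0)
        mean_psd = psd.power[:, sel].mean(axis=0)
        slope = np.polyfit(np.log(psd.freqs[sel]), np.log(mean_psd), 1)[0]
        assert abs(-slope - spec.background_exponent) <= 0.2

    def test_true_paf_matches_spec(self):
        spec = replace(SHORT, alpha=AlphaSpec(peak_hz=9.0))
        rec, truth = generate_recording(spec)
        assert truth.true_paf == 9.0
        assert peak_alpha_frequency(rec).mean_paf == 9.0


class TestArtifactInjection:
    def test_flat_channel_recovered_by_prep(self):
        spec = replace(SHORT, artifacts=(ArtifactSpec("flat_channel",
                                                      channel=3),))
        rec, truth = generate_recording(spec)
        assert truth.bad_channels == {3: "flat_channel"}
        res = prep_bad_channels(highpass(rec, 0.5))
        assert list(np.flatnonzero(res.per_criterion["flat"])) == [3]

    def test_line_noise_localized_to_channel(self):
        spec = replace(SHORT, seed=4,
                       line_noise=LineNoiseSpec(freq_hz=60.0,
                                                amplitude_uv=15.0,
                                                channels=(6,)))
        rec, _ = generate_recording(spec)
        res = faster_bad_channels(highpass(rec, 0.5))
        assert list(np.flatnonzero(res.per_criterion["powerline"])) == [6]

    def test_burst_epoch_recovered(self):
        spec = replace(SHORT, seed=5,
                       artifacts=(ArtifactSpec("burst_epoch", channel=2,
                                               epochs=(7,)),))
        rec, truth = generate_recording(spec)
        assert truth.bad_epochs == {7: "burst_epoch"}
        ep = epoch(highpass(rec, 0.5), 2.0)
        assert faster_bad_epochs(ep).bad[7]
        assert prep_bad_epochs(ep).bad[7]

    def test_blink_recovered_by_faster(self):
        spec = replace(SHORT, seed=6,
                       artifacts=(ArtifactSpec("blink", epochs=(2,)),))
        rec, truth = generate_recording(spec)
        assert truth.bad_epochs == {2: "blink"}
        ep = epoch(highpass(rec, 0.5), 2.0)
        assert faster_bad_epochs(ep).bad[2]


class TestSpecSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = replace(SHORT, artifacts=(
            ArtifactSpec("noisy_channel", channel=1, magnitude=4.0),
            ArtifactSpec("burst_epoch", channel=0, epochs=(3, 5)),
        ), line_noise=LineNoiseSpec(50.0, 2.0, (0, 1)))
        path = str(tmp_path / "spec.yaml")
        spec.to_yaml(path)
        assert SyntheticSpec.from_yaml(path) == spec

    def test_round_trip_preserves_output(self, tmp_path):
        path = str(tmp_path / "spec.yaml")
        SHORT.to_yaml(path)
        a, _ = generate_recording(SHORT)
        b, _ = generate_recording(SyntheticSpec.from_yaml(path))
        np.testing.assert_array_equal(a.data, b.data)


class TestCohort:
    def test_metadata_counts(self):
        base = SyntheticSpec(duration_s=10.0)
        pairs = generate_cohort(12, seed=0, base_spec=base,
                                teams=("A", "B", "C"))
        assert len(pairs) == 12
        teams = {rec.session.team_id for rec, _ in pairs}
        assert teams == {"A", "B", "C"}

    def test_cohort_deterministic(self):
        base = SyntheticSpec(duration_s=10.0)
        a = generate_cohort(3, seed=5, base_spec=base)
        b = generate_cohort(3, seed=5, base_spec=base)
        for (ra, _), (rb, _) in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)

    def test_age_paf_trend_recovered(self):
        # injected decline of peak alpha with age group reappears in
        # the recovered group means
        trend = {"15-24": 9.5, "25-44": 9.5, "45-64": 9.0, "65-74": 8.5}
        base = SyntheticSpec(duration_s=30.0)
        pairs = generate_cohort(24, seed=1, base_spec=base, paf_by_age=trend)
        by_age: dict[str, list[float]] = {}
        for rec, truth in pairs:
            paf = peak_alpha_frequency(rec).mean_paf
            by_age.setdefault(rec.session.age_group, []).append(paf)
        means = [np.mean(by_age[a]) for a in ("15-24", "25-44", "45-64", "65-74")
                 if a in by_age]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(3, seed=0, alpha_range=(11.0, 8.0))


class TestFractionalGaussianNoise:
    def test_unit_variance_white_case(self):
        rng = np.random.default_rng(0)
        x = fractional_gaussian_noise(0.5, 65536, rng)
        assert np.var(x) == pytest.approx(1.0, rel=0.05)

    def test_lag1_autocorrelation_sign(self):
        # persistent fGn has positive lag-1 autocorrelation,
        # anti-persistent negative
        rng = np.random.default_rng(1)
        for h, sign in ((0.8, 1), (0.2, -1)):
            x = fractional_gaussian_noise(h, 32768, rng)
            r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert np.sign(r1) == sign

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            fractional_gaussian_noise(1.5, 128, np.random.default_rng(0))
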