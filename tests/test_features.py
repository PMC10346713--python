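"""Preprocessing, epoching and feature computations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from trialcv import (
    FeatureTable,
    SessionConfig,
    TrialDataset,
    band_power,
    build_feature_table,
    differential_entropy,
    generate_session,
    preprocess,
    rms_and_variance,
    segment_trials,
    spectral_entropy,
    zscore_fit_apply,
)
from trialcv.features import EpochRecord
from trialcv.synthetic import TrialRecord, band_limited_noise

FS = 250.0


def sinusoid(freq, amp=1.0, duration=5.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def make_epochs(n_epochs=4, n_channels=3, fs=128.0, duration=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return [
        EpochRecord(
            sample_id=f"t{i // 2}e{i % 2}",
            trial_id=f"t{i // 2}",
            class_label=i % 2,
            epoch_index=i % 2,
            signal=rng.standard_normal((n_channels, int(fs * duration))),
            fs=fs,
        )
        for i in range(n_epochs)
    ]


class TestPreprocess:
    def _dataset(self, fs=500.0, n_channels=3, duration=4.0, seed=0):
        rng = np.random.default_rng(seed)
        cfg = SessionConfig(
            minutes_per_class=duration * 2 / 60,
            trial_duration_s=duration,
            fs=fs,
            n_channels=n_channels,
        )
        trials = [
            TrialRecord(f"t{i}", i % 2, "T4", i, rng.standard_normal((n_channels, int(fs * duration))), fs)
            for i in range(4)
        ]
        return TrialDataset(trials, cfg)

    def test_decimation_halves_sample_count(self):
        ds = preprocess(self._dataset(fs=500.0), target_fs=250.0, reref=False)
        assert all(t.signal.shape[1] == 1000 for t in ds.trials)
        assert ds.config.fs == 250.0

    def test_common_average_reference_zeroes_channel_mean(self):
        ds = preprocess(self._dataset(fs=500.0), target_fs=250.0, reref=True)
        for t in ds.trials:
            np.testing.assert_allclose(t.signal.mean(axis=0), 0.0, atol=1e-10)

    def test_60hz_tone_attenuated_by_20db(self):
        fs, dur = 500.0, 4.0
        tone = sinusoid(60.0, amp=1.0, duration=dur, fs=fs)
        cfg = SessionConfig(minutes_per_class=dur * 2 / 60, trial_duration_s=dur, fs=fs, n_channels=2)
        trials = [TrialRecord(f"t{i}", i % 2, "s", i, np.tile(tone, (2, 1)), fs) for i in range(2)]
        out = preprocess(TrialDataset(trials, cfg), target_fs=250.0, band=(0.5, 55.0), reref=False)
        p_in = band_power(tone, fs, (58.0, 62.0))
        p_out = band_power(out.trials[0].signal[0], 250.0, (58.0, 62.0))
        assert 10 * np.log10(p_in / p_out) >= 20.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(self._dataset(), target_fs=250.0, band=(0.5, 130.0))

    def test_single_channel_reref_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            preprocess(self._dataset(n_channels=1), reref=True)


class TestSegmentTrials:
    @pytest.mark.parametrize("trial_s,epoch_s,expected", [(60, 5, 12), (5, 5, 1), (15, 5, 3)])
    def test_epoch_counts(self, trial_s, epoch_s, expected):
        cfg = SessionConfig(minutes_per_class=1 if trial_s < 60 else 2, trial_duration_s=trial_s,
                            n_channels=2, fs=100.0, epoch_duration_s=epoch_s)
        ds = generate_session(cfg, seed=0)
        epochs = segment_trials(ds)
        per_trial = {}
        for e in epochs:
            per_trial[e.trial_id] = per_trial.get(e.trial_id, 0) + 1
        assert set(per_trial.values()) == {expected}

    def test_remainder_discarded_with_warning(self):
        fs = 100.0
        cfg = SessionConfig(minutes_per_class=17 / 30, trial_duration_s=17, n_channels=2, fs=fs)
        rng = np.random.default_rng(0)
        trials = [TrialRecord(f"t{i}", i % 2, "s", i, rng.standard_normal((2, 1700)), fs) for i in range(2)]
        with pytest.warns(UserWarning, match="remainder"):
            epochs = segment_trials(TrialDataset(trials, cfg), epoch_duration_s=5.0)
        assert len(epochs) == 6

    def test_epoch_longer_than_trial_rejected(self):
        cfg = SessionConfig(minutes_per_class=1 / 6, trial_duration_s=10, n_channels=2, fs=100.0)
        ds = generate_session(cfg, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            segment_trials(ds, epoch_duration_s=30.0)


class TestBandPower:
    def test_zero_signal_gives_zero(self):
        assert band_power(np.zeros(1250), FS, (8.0, 12.0)) == 0.0

    @pytest.mark.parametrize("method", ["welch", "periodogram"])
    @pytest.mark.parametrize("amp", [1.0, 3.0])
    def test_pure_tone_recovers_a_squared_over_two(self, amp, method):
        x = sinusoid(10.0, amp=amp)
        p = band_power(x, FS, (8.0, 12.0), psd_method=method)
        assert p == pytest.approx(amp**2 / 2.0, rel=0.05)

    def test_white_noise_matches_flat_spectrum_share(self):
        """Alpha-band power of unit white noise ~ bandwidth / Nyquist."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1000, 1250))
        p = band_power(x, FS, (8.0, 12.0))
        expected = 1.0 * (12.0 - 8.0) / (FS / 2.0)
        assert p.mean() == pytest.approx(expected, rel=0.02)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros(100), 100.0, (40.0, 60.0))

    def test_short_epoch_warns(self):
        with pytest.warns(UserWarning, match="cycles"):
            band_power(np.ones(125), FS, (1.0, 4.0))


class TestDifferentialEntropy:
    def test_unit_power_closed_form(self):
        x = sinusoid(10.0, amp=np.sqrt(2.0))  # band power 1
        de = differential_entropy(x, FS, (8.0, 12.0))
        assert de == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=0.05)

    def test_quadrupling_power_adds_ln2(self):
        x = sinusoid(10.0, amp=1.0)
        d1 = differential_entropy(x, FS, (8.0, 12.0))
        d2 = differential_entropy(2.0 * x, FS, (8.0, 12.0))
        assert d2 - d1 == pytest.approx(np.log(2.0), abs=1e-9)

    def test_band_limited_noise_matches_gaussian_formula(self):
        rng = np.random.default_rng(1)
        v = 2.5
        x = np.sqrt(v) * band_limited_noise(rng, 1250, FS, (8.0, 12.0), n_channels=500)
        de = differential_entropy(x, FS, (8.0, 12.0), psd_method="periodogram")
        assert de.mean() == pytest.approx(0.5 * np.log(2 * np.pi * np.e * v), abs=0.05)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            differential_entropy(np.zeros(1250), FS, (8.0, 12.0))

    def test_monotone_link_with_band_power(self):
        rng = np.random.default_rng(2)
        xs = [rng.standard_normal(1250) * s for s in (0.5, 1.0, 2.0, 5.0)]
        powers = [band_power(x, FS, (8.0, 12.0)) for x in xs]
        des = [differential_entropy(x, FS, (8.0, 12.0)) for x in xs]
        assert np.argsort(powers).tolist() == np.argsort(des).tolist()


class TestSpectralEntropy:
    def test_single_tone_is_degenerate(self):
        # an integer-period tone occupies exactly one periodogram bin
        x = sinusoid(2.0, duration=5.0)
        h = spectral_entropy(x, FS, (1.0, 4.0), psd_method="periodogram")
        assert h == pytest.approx(0.0, abs=1e-6)

    def test_in_band_white_noise_near_maximal(self):
        rng = np.random.default_rng(3)
        x = band_limited_noise(rng, 1250, FS, (1.0, 4.0), n_channels=1000)
        h = spectral_entropy(x, FS, (1.0, 4.0))
        assert 0.85 < h.mean() < 1.0
        # frozen Monte-Carlo reference for this estimator and design
        assert h.mean() == pytest.approx(0.959, abs=0.02)

    def test_bounds(self):
        rng = np.random.default_rng(4)
        h = spectral_entropy(rng.standard_normal((50, 1250)), FS, (1.0, 4.0))
        assert np.all(h >= 0.0) and np.all(h <= 1.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            spectral_entropy(np.ones(100), 100.0, (1.0, 1.5))

    def test_silent_band_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            spectral_entropy(np.zeros(1250), FS, (1.0, 4.0))


class TestRmsVariance:
    def test_constant_signal(self):
        rms, var = rms_and_variance(np.full(100, -3.0))
        assert rms == pytest.approx(3.0)
        assert var == 0.0

    def test_zero_signal(self):
        assert rms_and_variance(np.zeros(10)) == (0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        x=arrays(
            np.float64,
            st.integers(min_value=2, max_value=200),
            elements=st.floats(-1e3, 1e3),
        )
    )
    def test_identity_rms_sq_equals_var_plus_mean_sq(self, x):
        rms, var = rms_and_variance(x)
        assert rms**2 == pytest.approx(var + x.mean() ** 2, abs=1e-7 * max(1.0, rms**2))


class TestBuildFeatureTable:
    @pytest.mark.parametrize("n_channels,expected", [(62, 310), (32, 160)])
    def test_de_dimensionality(self, n_channels, expected):
        eps = make_epochs(n_epochs=4, n_channels=n_channels)
        table = build_feature_table(eps, "de")
        assert len(table.feature_names) == expected

    def test_bandpower_and_scalar_sets_dimensionality(self):
        eps = make_epochs(n_epochs=4, n_channels=4)
        assert len(build_feature_table(eps, "bandpower").feature_names) == 20
        assert len(build_feature_table(eps, "rms").feature_names) == 4
        assert len(build_feature_table(eps, "variance").feature_names) == 4
        assert len(build_feature_table(eps, "spectral_entropy").feature_names) == 4

    def test_mixed_shapes_rejected(self):
        eps = make_epochs(4, 3)
        eps[-1].signal = eps[-1].signal[:, :64]
        with pytest.raises(ValueError, match="mixed"):
            build_feature_table(eps, "rms")

    def test_permutation_equivariance(self):
        eps = make_epochs(n_epochs=6, n_channels=2)
        t1 = build_feature_table(eps, "bandpower")
        perm = [3, 0, 5, 1, 4, 2]
        t2 = build_feature_table([eps[i] for i in perm], "bandpower")
        np.testing.assert_allclose(t1.X[perm], t2.X)
        assert list(t1.sample_ids[perm]) == list(t2.sample_ids)

    def test_band_powers_sum_below_broadband_power(self):
        """The five disjoint bands cover most, never more, of the 0.5-55 Hz
        power of a bandpassed epoch."""
        cfg = SessionConfig(minutes_per_class=0.5, trial_duration_s=5, n_channels=2)
        ds = preprocess(generate_session(cfg, seed=0), band=(0.5, 55.0), reref=False)
        for e in segment_trials(ds):
            for ch in e.signal:
                total = band_power(ch, e.fs, (0.5, 55.0))
                band_sum = sum(band_power(ch, e.fs, b) for b in cfg.band_edges)
                assert band_sum <= total * (1 + 1e-9)
                assert band_sum >= 0.8 * total

    def test_csv_roundtrip(self, tmp_path):
        eps = make_epochs(4, 2)
        t1 = build_feature_table(eps, "bandpower")
        t1.to_csv(tmp_path / "t.csv")
        t2 = FeatureTable.from_csv(tmp_path / "t.csv")
        assert t2.feature_names == t1.feature_names
        assert t2.feature_set == "bandpower"
        np.testing.assert_allclose(t1.X, t2.X, rtol=1e-12)


class TestZscore:
    def _tables(self, seed=0):
        rng = np.random.default_rng(seed)

        def mk(prefix, n):
            frame = pd.DataFrame(
                {
                    "sample_id": [f"{prefix}{i}" for i in range(n)],
                    "trial_id": [f"{prefix}t{i // 2}" for i in range(n)],
                    "class_label": [i % 2 for i in range(n)],
                    "epoch_index": [0] * n,
                    "f0": rng.standard_normal(n) * 3 + 1,
                    "f1": rng.standard_normal(n),
                }
            )
            return FeatureTable(frame, ["f0", "f1"])

        return mk("a", 12), mk("b", 6)

    def test_train_fitted_train_is_standardized(self):
        tr, te = zscore_fit_apply(*self._tables())
        np.testing.assert_allclose(tr.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.X.std(axis=0), 1.0, atol=1e-10)
        assert abs(te.X.mean()) > 1e-6  # test follows train statistics

    def test_separate_mode_standardizes_test_too(self):
        tr, te = zscore_fit_apply(*self._tables(), mode="separate")
        np.testing.assert_allclose(te.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(te.X.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_centered_without_blowup(self):
        tr, te = self._tables()
        tr.frame["f1"] = 7.0
        te.frame["f1"] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            tr2, te2 = zscore_fit_apply(tr, te)
        np.testing.assert_allclose(tr2.frame["f1"], 0.0)
        np.testing.assert_allclose(te2.frame["f1"], 0.0)

    def test_feature_mismatch_rejected(self):
        tr, te = self._tables()
        te = te.select_features([0])
        with pytest.raises(ValueError, match="feature"):
            zscore_fit_apply(tr, te)
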