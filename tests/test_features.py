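"""Spectral feature extraction: timing identities, normalization, lagging."""

from types import SimpleNamespace

import numpy as np
import pytest

from gripstate.features import (
    DEFAULT_BANDS,
    BandDefinition,
    FeatureTensor,
    build_lagged_design,
    compute_band_features,
    event_aligned_raster,
    spectrogram_power,
)


def _session(signal, fs=2000.0):
    return SimpleNamespace(signal=np.atleast_2d(signal), fs_hz=fs, channels=None)


class TestTimingIdentities:
    def test_frequency_resolution_is_fs_over_window(self):
        x = np.random.default_rng(0).standard_normal(4000)
        _, freqs, _ = spectrogram_power(x, 2000.0, window_s=0.256)
        df = freqs[1] - freqs[0]
        assert df == pytest.approx(2000.0 / 512)  # 3.90625 Hz, printed as 3.9

    def test_hop_of_25_ms_from_231_ms_overlap(self):
        x = np.random.default_rng(0).standard_normal(4000)
        _, _, times = spectrogram_power(x, 2000.0, window_s=0.256, step_s=0.256 - 0.231)
        assert np.allclose(np.diff(times), 0.025)

    def test_bin_count_identity(self):
        rng = np.random.default_rng(1)
        for n in (512, 513, 5000, 12345):
            x = rng.standard_normal(n)
            psd, _, _ = spectrogram_power(x, 2000.0)
            assert psd.shape[0] == (n - 512) // 50 + 1


class TestBandFeatures:
    def test_white_noise_features_have_zero_mean(self):
        rng = np.random.default_rng(2)
        ft = compute_band_features(_session(rng.standard_normal((3, 200000))))
        n = ft.n_bins
        se = ft.values.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(ft.values.mean(axis=0)) < 3 * se + 1e-12)

    def test_band_outside_resolvable_range_raises(self):
        x = np.random.default_rng(0).standard_normal(4000)
        with pytest.raises(ValueError, match="lo < hi < fs/2"):
            compute_band_features(
                _session(x), bands=(BandDefinition("bad", 900.0, 1100.0),)
            )

    def test_nonfinite_sample_raises(self):
        x = np.zeros(4000)
        x[1234] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_band_features(_session(x))

    def test_feature_order_is_electrode_major(self, small_features):
        idx = small_features.feature_index
        assert idx[0] == (0, "low") and idx[1] == (0, "high")
        assert idx[2] == (1, "low")

    def test_unnormalized_band_power_matches_filter_variance(self):
        """Welch-scaled band power from the windowed-FFT path agrees within
        1% with brickwall-filter-then-variance on long stationary noise."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2**19)
        psd, freqs, _ = spectrogram_power(x, 2000.0)
        m = (freqs >= 8) & (freqs <= 55)
        df = freqs[1] - freqs[0]
        fft_band_power = (psd[:, m].sum(axis=1) * df).mean()
        # independent oracle: zero out everything outside the same bins
        X = np.fft.rfft(x)
        fx = np.fft.rfftfreq(len(x), 1 / 2000.0)
        keep = (fx >= freqs[m][0] - df / 2) & (fx <= freqs[m][-1] + df / 2)
        xb = np.fft.irfft(X * keep, len(x))
        assert fft_band_power == pytest.approx(xb.var(), rel=0.01)

    def test_shift_equivariance_by_whole_hops(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40000)
        k = 3  # hops
        a = compute_band_features(_session(x), normalize=False)
        b = compute_band_features(_session(np.r_[np.zeros(k * 50), x]), normalize=False)
        assert np.allclose(a.values[: a.n_bins - k], b.values[k : a.n_bins], atol=1e-9)


class TestLaggedDesign:
    def test_column_count_formula(self, small_features):
        d = build_lagged_design(small_features, 10)
        n_elec = small_features.n_features // 2
        assert d.values.shape[1] == 2 * n_elec * 10

    def test_single_lag_is_identity(self, small_features):
        d = build_lagged_design(small_features, 1)
        assert np.array_equal(d.values, small_features.values)
        assert np.array_equal(d.bin_times, small_features.bin_times)

    def test_constant_features_give_identical_rows(self):
        ft = FeatureTensor(
            np.ones((30, 4)), np.arange(30) * 0.025, 0.256, 0.025,
            [(0, "low"), (0, "high"), (1, "low"), (1, "high")],
        )
        d = build_lagged_design(ft, 5)
        assert np.all(d.values == d.values[0])

    def test_causality_rows_ignore_future(self, small_features):
        d1 = build_lagged_design(small_features, 10)
        tampered = FeatureTensor(
            small_features.values.copy(), small_features.bin_times,
            small_features.window_s, small_features.step_s,
            small_features.feature_index,
        )
        cut = 200
        tampered.values[cut:] = 999.0
        d2 = build_lagged_design(tampered, 10)
        assert np.array_equal(d1.values[: cut - 9], d2.values[: cut - 9])

    def test_too_many_lags_raises(self, small_features):
        with pytest.raises(ValueError, match="exceeds"):
            build_lagged_design(small_features, small_features.n_bins + 1)


class TestRaster:
    def test_constant_feature_rasterizes_to_zeros(self):
        ft = FeatureTensor(
            np.ones((200, 2)), np.arange(200) * 0.025 + 0.128, 0.256, 0.025,
            [(0, "low"), (0, "high")],
        )
        r, rel, kept = event_aligned_raster(ft, 0, np.array([2.0, 3.0]), 0.5, 0.5)
        assert np.all(r == 0)

    def test_edge_events_are_excluded_with_warning(self):
        ft = FeatureTensor(
            np.random.default_rng(0).standard_normal((200, 1)),
            np.arange(200) * 0.025 + 0.128, 0.256, 0.025, [(0, "low")],
        )
        with pytest.warns(UserWarning, match="excluded"):
            r, _, kept = event_aligned_raster(ft, 0, np.array([0.2, 2.5]), 1.0, 1.0)
        assert list(kept) == [1]

    def test_sort_key_orders_rows_like_oracle(self, small_features, small_session):
        _, _, trials, _ = small_session
        gap = (trials["force_onset_s"] - trials["movement_onset_s"]).to_numpy()
        r, _, kept = event_aligned_raster(
            small_features, 0, trials["movement_onset_s"].to_numpy(),
            0.5, 0.5, sort_key=gap,
        )
        assert np.all(np.diff(gap[kept]) >= 0)

    def test_force_locked_electrode_transitions_at_force_onset(self):
        """An electrode driven only by force shows its high-band power rise
        within one bin of the true force onset."""
        from gripstate.simulate import SimulationConfig, simulate_session

        cfg = SimulationConfig(
            n_trials=30, n_rows=4, n_cols=4, snr=10.0, seed=21,
            lock_probs=(0.0, 1.0, 0.0), planted_peak_shift_mm=0.0,
            latent_gain=0.05,
        )
        session, trials, truth = simulate_session(cfg)
        ft = compute_band_features(session)
        elec = int(truth.force_gain_map.argmax())
        col = int(ft.columns_for_electrode(elec)[1])  # high band
        r, rel, kept = event_aligned_raster(
            ft, col, trials["force_onset_s"].to_numpy(), 0.75, 0.75
        )
        mean_tc = r.mean(axis=0)
        smooth = np.convolve(mean_tc, np.ones(5) / 5, mode="valid")
        t_steepest = rel[2:-2][np.argmax(np.diff(smooth)) + 1]
        # steepest rise falls inside the 0.3-s contact ramp after onset
        assert 0.0 - 0.025 <= t_steepest <= 0.3 + 0.025
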