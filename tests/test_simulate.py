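"""Synthetic session generator: geometry, task structure, spectral content."""

import numpy as np
import pytest
from scipy import signal as sps

from gripstate.simulate import (
    HIGH_BAND,
    LOW_BAND,
    MODE_FORCE,
    MODE_MOVEMENT,
    MODE_PREMOVE,
    SimulationConfig,
    _band_carrier,
    plant_gain_maps,
    simulate_session,
)


class TestPlantGainMaps:
    def test_zero_shift_means_identical_argmax(self):
        mov, frc = plant_gain_maps(8, 8, 4.0, 0.0, seed=0)
        assert mov.argmax() == frc.argmax()

    @pytest.mark.parametrize(
        "shift_mm,expected_sites",
        [(8.0, 2.0), (4.0, 1.0), (np.sqrt(2) * 4.0, np.sqrt(2))],
    )
    def test_peak_separation_in_grid_units(self, shift_mm, expected_sites):
        mov, frc = plant_gain_maps(8, 8, 4.0, shift_mm, seed=3)
        r0, c0 = np.unravel_index(mov.argmax(), mov.shape)
        r1, c1 = np.unravel_index(frc.argmax(), frc.shape)
        assert np.hypot(r1 - r0, c1 - c0) == pytest.approx(expected_sites)

    def test_maps_unimodal_nonnegative_and_max_one(self):
        for m in plant_gain_maps(4, 8, 4.0, 8.0, seed=1):
            assert m.min() >= 0
            assert m.max() == pytest.approx(1.0)

    def test_impossible_shift_lists_achievable(self):
        with pytest.raises(ValueError, match="achievable"):
            plant_gain_maps(2, 2, 4.0, 100.0, seed=0)
        with pytest.raises(ValueError, match="achievable"):
            plant_gain_maps(2, 2, 4.0, 3.0, seed=0)  # not on the lattice


class TestSessionStructure:
    def test_trial_count_passthrough(self):
        cfg = SimulationConfig(n_trials=60, n_rows=2, n_cols=2, planted_peak_shift_mm=4.0, seed=0)
        _, trials, _ = simulate_session(cfg)
        assert len(trials) == 60

    def test_intertrial_delay_exact_with_zero_jitter(self):
        cfg = SimulationConfig(
            n_trials=5, n_rows=2, n_cols=2, iti_s=1.0, planted_peak_shift_mm=4.0,
            premove_jitter_s=0.0, move_jitter_s=0.0, force_jitter_s=0.0, seed=0,
        )
        _, trials, _ = simulate_session(cfg)
        gaps = trials["cue_time_s"].to_numpy()[1:] - trials["force_end_s"].to_numpy()[:-1]
        assert np.allclose(gaps, 1.0)

    def test_mode_ordering_within_each_trial(self, small_session):
        _, session, trials, truth = small_session
        fs = session.fs_hz
        for _, tr in trials.iterrows():
            seg = truth.true_mode_labels[
                int(tr["cue_time_s"] * fs) : int((tr["force_onset_s"] + 0.5) * fs)
            ]
            seg = seg[seg != 0]
            # premovement block, then movement, then force, no interleaving
            changes = seg[np.flatnonzero(np.diff(seg)) + 1]
            assert list(changes) == [MODE_MOVEMENT, MODE_FORCE]
            assert seg[0] == MODE_PREMOVE

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_trials=3, n_rows=2, n_cols=2, planted_peak_shift_mm=4.0, seed=42)
        s1, t1, g1 = simulate_session(cfg)
        s2, t2, g2 = simulate_session(cfg)
        assert np.array_equal(s1.signal, s2.signal)
        assert np.array_equal(s1.force, s2.force)
        assert t1.equals(t2)
        assert np.array_equal(g1.latent_traces, g2.latent_traces)

    def test_kinematics_rise_and_plateau(self, small_session):
        _, session, trials, truth = small_session
        fs = session.fs_hz
        tr = trials.iloc[2]
        flex = truth.flexion
        pre = flex[int((tr["cue_time_s"]) * fs) : int(tr["movement_onset_s"] * fs)]
        plateau = flex[int((tr["force_onset_s"] + 0.1) * fs) : int((tr["force_end_s"] - 0.1) * fs)]
        assert np.abs(pre).max() < 1e-9
        assert plateau.std() < 1e-9 and plateau.mean() > 0.1

    def test_force_zero_until_onset_then_ramps_to_target(self, small_session):
        _, session, trials, _ = small_session
        fs = session.fs_hz
        for _, tr in trials.iloc[:5].iterrows():
            before = session.force[int(tr["cue_time_s"] * fs) : int(tr["force_onset_s"] * fs)]
            assert np.abs(before).max() < 1e-9
            plateau = session.force[
                int((tr["force_onset_s"] + 0.35) * fs) : int((tr["force_end_s"] - 0.35) * fs)
            ]
            assert plateau.max() == pytest.approx(tr["force_target"], rel=1e-6)


class TestSpectralContent:
    @pytest.mark.parametrize("kind", ["noise", "multisine"])
    @pytest.mark.parametrize("band", [LOW_BAND, HIGH_BAND])
    def test_carrier_power_confined_to_band(self, kind, band):
        rng = np.random.default_rng(0)
        x = _band_carrier(rng, band, 2000.0, 2**17, kind)
        f, p = sps.periodogram(x, fs=2000.0)
        inband = p[(f >= band[0] - 2) & (f <= band[1] + 2)].sum()
        assert inband / p.sum() > 0.95

    def test_zero_gain_electrode_has_flat_features(self):
        """No planted modulation and no noise -> band features essentially
        constant (only spectral-leakage ripple of the deterministic
        carrier remains)."""
        from gripstate.features import compute_band_features

        cfg = SimulationConfig(
            n_trials=8, n_rows=4, n_cols=4, snr=np.inf, carrier="multisine",
            planted_peak_shift_mm=0.0, latent_gain=0.3, seed=9,
        )
        session, trials, truth = simulate_session(cfg)
        gains = np.maximum(
            truth.movement_gain_map.ravel(), truth.force_gain_map.ravel()
        )
        feats = compute_band_features(session)
        quiet = int(np.argmin(gains))
        active = int(np.argmax(gains))
        var_quiet = feats.values[:, feats.columns_for_electrode(quiet)].var(axis=0)
        var_active = feats.values[:, feats.columns_for_electrode(active)].var(axis=0)
        assert gains[quiet] == 0.0  # corner electrode outside both bumps
        assert var_quiet.max() < 1e-8
        assert var_quiet.max() < 1e-4 * var_active.max()

    def test_feature_rank_matches_planted_dimensions(self):
        """Without noise the log band-power matrix spans the planted latents
        plus the two mode envelopes (rank latent_dim + 2, by SVD)."""
        from gripstate.features import compute_band_features

        cfg = SimulationConfig(
            n_trials=10, n_rows=3, n_cols=3, snr=np.inf, carrier="multisine",
            planted_peak_shift_mm=4.0, latent_dim=3, lock_probs=(0.0, 0.0, 1.0),
            seed=2,
        )
        session, _, _ = simulate_session(cfg)
        feats = compute_band_features(session)
        v = feats.values - feats.values.mean(axis=0)
        sv = np.linalg.svd(v, compute_uv=False)
        strong = (sv > 0.1 * sv[0]).sum()
        assert strong == cfg.latent_dim + 2
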