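"""Shared fixtures: synthetic sessions and a trained latent-dynamics model.

Everything is generated at test time from seeds; session-scoped fixtures
amortize the expensive pieces (a full noiseless session, one trained
sequential autoencoder) across the modules that need them.
"""

import numpy as np
import pytest

from gripstate.behavior import detect_onsets, kinematic_pc1
from gripstate.features import build_lagged_design, compute_band_features
from gripstate.lfads import fit_gaussian_lfads
from gripstate.simulate import SimulationConfig, simulate_latent_features, simulate_session


@pytest.fixture(scope="session")
def noiseless_session():
    """60-trial, 16-electrode session without additive noise: the decoder
    recovery benchmark."""
    cfg = SimulationConfig(n_trials=60, n_rows=4, n_cols=4, snr=np.inf, seed=11)
    session, trials, truth = simulate_session(cfg)
    return cfg, session, trials, truth


@pytest.fixture(scope="session")
def noiseless_features(noiseless_session):
    _, session, _, _ = noiseless_session
    feats = compute_band_features(session)
    design = build_lagged_design(feats, 10)
    return feats, design


@pytest.fixture(scope="session")
def small_session():
    """20-trial, 16-electrode session at moderate noise for behavioral and
    NVA checks."""
    cfg = SimulationConfig(n_trials=20, n_rows=4, n_cols=4, snr=5.0, seed=5)
    session, trials, truth = simulate_session(cfg)
    return cfg, session, trials, truth


@pytest.fixture(scope="session")
def small_features(small_session):
    _, session, _, _ = small_session
    return compute_band_features(session)


@pytest.fixture(scope="session")
def detected_trials(small_session):
    _, session, _, _ = small_session
    pc1 = kinematic_pc1(session.kinematics)
    return detect_onsets(pc1, session.force, session.cue_times_s, session.fs_hz)


@pytest.fixture(scope="session")
def latent_benchmark():
    """Linear-Gaussian latent benchmark plus one trained model."""
    x, z = simulate_latent_features(
        n_trials=60, n_features=40, latent_dim=3, n_bins=50, noise_sd=0.5, seed=0
    )
    model = fit_gaussian_lfads(x, n_factors=8, seed=1, epochs=300)
    return x, z, model
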