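#!/usr/bin/env python
"""Denoise the spectral features with the Gaussian-emission sequential
autoencoder and count the PCs needed for 90% variance, raw vs denoised.

Fits one model per band on z-scored features windowed around force onset
and writes the latent trajectories summary to results/.
"""

import argparse
import json
from pathlib import Path

from gripstate.behavior import detect_onsets, kinematic_pc1
from gripstate.features import compute_band_features
from gripstate.lfads import denoise, fit_gaussian_lfads, pcs_for_variance, trial_feature_windows
from gripstate.session_io import read_session

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
ap.add_argument("--epochs", type=int, default=200)
ap.add_argument("--seed", type=int, default=7)
args = ap.parse_args()

session, _, _ = read_session(args.results / "session.h5")
feats = compute_band_features(session)
pc1 = kinematic_pc1(session.kinematics)
trials = detect_onsets(pc1, session.force, session.cue_times_s, session.fs_hz)

out = {}
for band in ("high", "low"):
    win = trial_feature_windows(feats, trials, band=band)
    model = fit_gaussian_lfads(win, seed=args.seed, epochs=args.epochs)
    traj = denoise(model, win)
    flat_raw = win.values.reshape(-1, win.values.shape[-1])
    flat_den = traj.mu.reshape(-1, traj.mu.shape[-1])
    out[band] = {
        "n_factors": model.n_factors,
        "final_elbo": round(float(model.elbo_history[-1]), 2),
        "pcs90_raw": pcs_for_variance(flat_raw),
        "pcs90_denoised": pcs_for_variance(flat_den),
        "n_trials": int(win.values.shape[0]),
    }
    print(f"{band} band: {model.n_factors} factors; PCs for 90% variance: "
          f"{out[band]['pcs90_raw']} raw -> {out[band]['pcs90_denoised']} denoised")

(args.results / "latent_dynamics.json").write_text(json.dumps(out, indent=2))
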