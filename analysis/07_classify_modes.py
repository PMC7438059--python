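#!/usr/bin/env python
"""Classify every labeled 25-ms bin as premovement / movement / force.

Uses the lagged band-power features (and, when available, the denoised
features from the latent-dynamics stage), reports median accuracy across
5 blocked folds and an optional permutation chance level.
"""

import argparse
import json
from pathlib import Path

from gripstate.behavior import UNLABELED, detect_onsets, kinematic_pc1, label_modes
from gripstate.classify import chance_level, classify_modes
from gripstate.features import build_lagged_design, compute_band_features
from gripstate.session_io import read_session

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
ap.add_argument("--method", choices=["svm", "bagged_trees"], default="svm")
ap.add_argument("--shuffles", type=int, default=200)
ap.add_argument("--seed", type=int, default=7)
args = ap.parse_args()

session, _, _ = read_session(args.results / "session.h5")
feats = compute_band_features(session)
design = build_lagged_design(feats, 10)
pc1 = kinematic_pc1(session.kinematics)
trials = detect_onsets(pc1, session.force, session.cue_times_s, session.fs_hz)
labels = label_modes(trials, feats.bin_times)

lab = labels.codes[9:]
tid = labels.trial_of_bin[9:]
keep = lab != UNLABELED
res = classify_modes(design.values[keep], lab[keep], method=args.method,
                     n_folds=5, seed=args.seed)
out = {
    "method": args.method,
    "fold_accuracy": res.fold_accuracy.round(4).tolist(),
    "accuracy_median_pct": round(100 * res.median, 1),
    "accuracy_iqr_pct": round(100 * res.iqr, 1),
    "confusion": res.confusion.tolist(),
}
print(f"{args.method}: accuracy {out['accuracy_median_pct']}% "
      f"(IQR {out['accuracy_iqr_pct']}%) over {int(keep.sum())} labeled bins")

if args.shuffles:
    chance = chance_level(design.values[keep], lab[keep],
                          n_shuffles=args.shuffles, seed=args.seed,
                          method=args.method, trial_ids=tid[keep])
    out["chance_mean_pct"] = round(100 * float(chance.mean()), 1)
    out["chance_p975_pct"] = round(100 * float(__import__("numpy").percentile(chance, 97.5)), 1)
    print(f"chance level {out['chance_mean_pct']}% "
          f"(97.5th percentile {out['chance_p975_pct']}%, {args.shuffles} shuffles)")

(args.results / "mode_classification.json").write_text(json.dumps(out, indent=2))
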