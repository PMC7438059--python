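#!/usr/bin/env python
"""Decode continuous finger movement and isometric force from band power.

Fits independent ridge-regularized Wiener cascades for the two targets with
11-fold blocked cross-validation and writes per-fold FVAFs to results/.
"""

import argparse
import json
from pathlib import Path

from gripstate.behavior import kinematic_pc1
from gripstate.decoding import crossval_decode, sample_trace_at_bins
from gripstate.features import build_lagged_design, compute_band_features
from gripstate.session_io import read_session

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
ap.add_argument("--folds", type=int, default=11)
args = ap.parse_args()

session, _, _ = read_session(args.results / "session.h5")
feats = compute_band_features(session)
design = build_lagged_design(feats, 10)
pc1 = kinematic_pc1(session.kinematics)

out = {}
for name, trace in (("movement", pc1), ("force", session.force)):
    y = sample_trace_at_bins(trace, session.fs_hz, design.bin_times)
    cv = crossval_decode(design, y, n_folds=args.folds)
    out[name] = {
        "fold_fvaf": cv.fold_fvaf.round(4).tolist(),
        "median": round(cv.median, 4),
        "iqr": round(cv.iqr, 4),
    }
    print(f"{name}: FVAF median {cv.median:.2f} +/- {cv.iqr:.2f} IQR "
          f"({args.folds} folds, {design.values.shape[1]} design columns)")

(args.results / "continuous_decoding.json").write_text(json.dumps(out, indent=2))
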