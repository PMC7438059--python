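#!/usr/bin/env python
"""Neural vector angle analysis: cluster features, compute per-trial NVA
time courses, and test mode differences.

Writes per-trial angle traces (CSV) and the Kruskal-Wallis summaries to
results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gripstate.behavior import detect_onsets, kinematic_pc1
from gripstate.features import compute_band_features
from gripstate.nva import (
    compare_modes_nva,
    nva_time_course,
    select_feature_clusters,
    trial_averaged_traces,
)
from gripstate.session_io import read_session

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
ap.add_argument("--seed", type=int, default=7)
args = ap.parse_args()

session, _, _ = read_session(args.results / "session.h5")
feats = compute_band_features(session)
pc1 = kinematic_pc1(session.kinematics)
trials = detect_onsets(pc1, session.force, session.cue_times_s, session.fs_hz)

avg, _ = trial_averaged_traces(feats, trials)
bands = [b for _, b in feats.feature_index]
fc = select_feature_clusters(avg, bands, k=3, seed=args.seed)
res = nva_time_course(feats, fc, trials)
tests = compare_modes_nva(res, trials)

rows = []
for tag, th in res.theta.items():
    for i, ti in enumerate(res.trial_index):
        for j, t_rel in enumerate(res.rel_times):
            rows.append(dict(band=tag, trial=int(ti), rel_time_s=round(t_rel, 3),
                             theta_deg=th[i, j]))
pd.DataFrame(rows).to_csv(args.results / "nva_traces.csv", index=False)
(args.results / "nva_tests.json").write_text(json.dumps(tests, indent=2))

for tag in ("low", "high"):
    t = tests[tag]
    meds = ", ".join(f"{m} {t['medians'][m]:.0f} deg" for m in t["modes"])
    print(f"{tag} band: Kruskal-Wallis H={t['H']:.1f}, p={t['p']:.2e}; medians: {meds}")
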