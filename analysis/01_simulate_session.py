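#!/usr/bin/env python
"""Generate the study's synthetic movement-force session and save it.

Writes the session container (HDF5), the ground-truth trial table (CSV) and
a short summary of the task schedule to results/.
"""

import argparse
from pathlib import Path

from gripstate.session_io import write_session
from gripstate.simulate import SimulationConfig, simulate_session

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=7)
ap.add_argument("--n-trials", type=int, default=60)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
cfg = SimulationConfig(n_trials=args.n_trials, seed=args.seed)
session, trials, truth = simulate_session(cfg)
write_session(session, args.out / "session.h5", trials=trials, truth=truth)
trials.to_csv(args.out / "true_trials.csv", index=False)

print(f"simulated {len(trials)} trials over {session.duration_s:.1f} s "
      f"({session.signal.shape[0]} electrodes at {session.fs_hz:.0f} Hz)")
print(f"planted peak shift: {cfg.planted_peak_shift_mm} mm; "
      f"latent dimensions: {cfg.latent_dim}; SNR: {cfg.snr}")
print(f"wrote {args.out / 'session.h5'} and {args.out / 'true_trials.csv'}")
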