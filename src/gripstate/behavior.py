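"""Movement signal derivation, onset detection, and behavioral-mode labels.

Behavioral modes per trial: *premovement* from the cue to flexion onset,
*movement* from flexion onset to force-sensor contact, and *force* for the
first 0.5 s of isometric force.  Bins outside those windows stay unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModeLabels",
    "UNLABELED",
    "PREMOVEMENT",
    "MOVEMENT",
    "FORCE",
    "MODE_NAMES",
    "kinematic_pc1",
    "detect_onsets",
    "label_modes",
]

UNLABELED, PREMOVEMENT, MOVEMENT, FORCE = 0, 1, 2, 3
MODE_NAMES = {UNLABELED: "unlabeled", PREMOVEMENT: "premovement",
              MOVEMENT: "movement", FORCE: "force"}


@dataclass
class ModeLabels:
    """Per-feature-bin behavioral mode codes plus the trial each bin serves."""

    codes: np.ndarray  # (n_bins,) int8
    bin_times: np.ndarray
    trial_of_bin: np.ndarray  # (n_bins,) trial index, -1 when unlabeled

    def labeled(self) -> np.ndarray:
        return self.codes != UNLABELED


def kinematic_pc1(sensor_traces: np.ndarray) -> np.ndarray:
    """First principal component score of the glove sensors over time.

    ``sensor_traces`` is (n_sensors, n_samples).  The score is sign-oriented
    so that flexion (shared positive deflection of the sensors) is positive:
    the PC1 loading vector is flipped if its entries sum negative.
    """
    x = np.atleast_2d(np.asarray(sensor_traces, dtype=float))
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance sensor(s): {np.flatnonzero(sd == 0).tolist()}")
    xc = x - x.mean(axis=1, keepdims=True)
    # PCA via SVD on sensors-as-variables
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    loading = u[:, 0]
    score = s[0] * vt[0]
    flip = np.sign(loading.sum()) or np.sign(loading[np.argmax(np.abs(loading))])
    return flip * score


def detect_onsets(
    movement_signal: np.ndarray,
    force: np.ndarray,
    cue_times: np.ndarray,
    fs_hz: float,
    baseline_s: float = 0.3,
    threshold_sd: float = 3.0,
    sustain_s: float = 0.05,
    contact_frac: float = 0.02,
    timeout_s: float = 2.0,
    backtrack_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-trial movement/force onsets by sustained threshold crossing.

    Movement onset is the first time after the cue where the movement signal
    exceeds (baseline mean + ``threshold_sd`` * baseline SD) continuously for
    ``sustain_s``; the baseline is the ``baseline_s`` window before the cue.
    The crossing is then backtracked to the last sample within
    ``backtrack_sd`` baseline SDs, which removes the ramp-delay bias of a
    plain threshold rule.  Force onset is the first sustained crossing of
    ``contact_frac`` of the session's maximum force, backtracked the same
    way toward zero.  Trials without both crossings before the next cue are
    flagged invalid.
    """
    mvt = np.asarray(movement_signal, dtype=float)
    frc = np.asarray(force, dtype=float)
    cues = np.asarray(cue_times, dtype=float)
    if np.any(np.diff(cues) <= 0):
        raise ValueError("cue times must be strictly increasing")
    n = len(mvt)
    sustain = max(int(round(sustain_s * fs_hz)), 1)
    f_thresh = contact_frac * frc.max() if frc.max() > 0 else np.inf

    def first_sustained(x, start, stop, thresh, floor):
        above = x[start:stop] > thresh
        if not above.any():
            return None
        # run-length scan for the first run of >= sustain samples
        idx = np.flatnonzero(above)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if len(run) >= sustain:
                k = start + run[0]
                while k > start and x[k - 1] > floor:
                    k -= 1
                return k
        return None

    rows = []
    bounds = np.append(cues, n / fs_hz)
    for i, cue in enumerate(cues):
        c0 = int(round(cue * fs_hz))
        c1 = min(int(round(bounds[i + 1] * fs_hz)), n)
        b0 = max(c0 - int(round(baseline_s * fs_hz)), 0)
        base = mvt[b0:c0]
        thr = base.mean() + threshold_sd * base.std()
        floor = base.mean() + backtrack_sd * base.std()
        m_idx = first_sustained(mvt, c0, c1, thr, floor)
        f_idx = first_sustained(
            frc, m_idx if m_idx is not None else c0, c1, f_thresh, 0.0
        )
        valid = m_idx is not None and f_idx is not None and f_idx > m_idx
        if valid:
            pk = c0 + int(np.argmax(frc[c0:c1]))
            mo, fo = m_idx / fs_hz, f_idx / fs_hz
            outcome = "matched" if (pk / fs_hz - fo) <= timeout_s else "timeout"
        else:
            mo = fo = np.nan
            pk = -1
            outcome = "invalid"
        rows.append(
            {
                "cue_time_s": cue,
                "movement_onset_s": mo,
                "force_onset_s": fo,
                "peak_force_time_s": pk / fs_hz if pk >= 0 else np.nan,
                "force_target": frc[pk] if pk >= 0 else np.nan,
                "outcome": outcome,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)


def label_modes(
    trials: pd.DataFrame, bin_times: np.ndarray, force_window_s: float = 0.5
) -> ModeLabels:
    """Assign each feature bin to a behavioral mode by its center time.

    Windows are half-open: premovement [cue, movement_onset), movement
    [movement_onset, force_onset), force [force_onset, force_onset +
    ``force_window_s``).  Invalid trials contribute no labels; trials whose
    movement window is empty are skipped the same way.  Overlapping trials
    raise.
    """
    bt = np.asarray(bin_times, dtype=float)
    codes = np.zeros(len(bt), dtype=np.int8)
    trial_of = np.full(len(bt), -1, dtype=int)
    valid = trials[trials["valid"]].reset_index()
    starts = valid["cue_time_s"].to_numpy()
    ends = valid["force_onset_s"].to_numpy() + force_window_s
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("trials overlap: a cue precedes the previous force window end")
    for _, tr in valid.iterrows():
        if not (tr["cue_time_s"] < tr["movement_onset_s"] < tr["force_onset_s"]):
            continue  # degenerate trial (e.g. zero movement bins)
        spans = (
            (PREMOVEMENT, tr["cue_time_s"], tr["movement_onset_s"]),
            (MOVEMENT, tr["movement_onset_s"], tr["force_onset_s"]),
            (FORCE, tr["force_onset_s"], tr["force_onset_s"] + force_window_s),
        )
        for code, lo, hi in spans:
            m = (bt >= lo) & (bt < hi)
            codes[m] = code
            trial_of[m] = int(tr["index"])
    return ModeLabels(codes=codes, bin_times=bt, trial_of_bin=trial_of)
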