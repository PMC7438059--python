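"""HDF5 session container I/O.

Layout (schema version 1):

    /signal            channels x samples, float64
    /kinematics        sensors x samples
    /force             samples
    /cue_times_s       trials
    /channels/<col>    one dataset per channel-table column
    /ground_truth/...  optional parallel group written by the simulator
    attrs: fs_hz, schema_version, seed, config_yaml, data_hash

The data hash covers the array payloads; a mismatch on read (e.g. after a
manual edit) produces a warning, not an error.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import h5py
import numpy as np
import pandas as pd

from .simulate import GroundTruth, SessionData

__all__ = ["read_session", "write_session", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1
_MANDATORY = ("signal", "kinematics", "force", "cue_times_s", "channels")


def _payload_hash(session: SessionData) -> str:
    h = hashlib.sha256()
    for arr in (session.signal, session.kinematics, session.force, session.cue_times_s):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def write_session(
    session: SessionData,
    path,
    trials: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs_hz"] = session.fs_hz
        f.attrs["data_hash"] = _payload_hash(session)
        f.attrs["provenance"] = json.dumps(session.provenance, default=str)
        f.create_dataset("signal", data=session.signal)
        f.create_dataset("kinematics", data=session.kinematics)
        f.create_dataset("force", data=session.force)
        f.create_dataset("cue_times_s", data=session.cue_times_s)
        ch = f.create_group("channels")
        for col in session.channels.columns:
            ch.create_dataset(col, data=session.channels[col].to_numpy())
        if trials is not None:
            tg = f.create_group("trials")
            for col in trials.columns:
                data = trials[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                tg.create_dataset(col, data=data)
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("movement_gain_map", data=truth.movement_gain_map)
            g.create_dataset("force_gain_map", data=truth.force_gain_map)
            g.create_dataset("latent_traces", data=truth.latent_traces)
            g.create_dataset("true_mode_labels", data=truth.true_mode_labels)
            g.create_dataset("flexion", data=truth.flexion)
            g.create_dataset("lock_class", data=truth.lock_class)
            og = g.create_group("true_onsets")
            for col in truth.true_onsets.columns:
                og.create_dataset(col, data=truth.true_onsets[col].to_numpy())


def read_session(path):
    """Read a session file; returns ``(session, trials, truth)`` where the
    last two are None when the file holds no such groups."""
    with h5py.File(path, "r") as f:
        ver = int(f.attrs.get("schema_version", -1))
        if ver != SCHEMA_VERSION:
            raise ValueError(
                f"schema version mismatch: expected {SCHEMA_VERSION}, found {ver}"
            )
        missing = [k for k in _MANDATORY if k not in f]
        if missing:
            raise ValueError(f"session file missing mandatory group(s): {missing}")
        channels = pd.DataFrame({c: f["channels"][c][()] for c in f["channels"]})
        session = SessionData(
            signal=f["signal"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            channels=channels,
            kinematics=f["kinematics"][()],
            force=f["force"][()],
            cue_times_s=f["cue_times_s"][()],
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )
        stored = f.attrs.get("data_hash", "")
        if stored and stored != _payload_hash(session):
            warnings.warn("session payload hash mismatch: file was modified after writing")
        trials = truth = None
        if "trials" in f:
            cols = {}
            for c in f["trials"]:
                v = f["trials"][c][()]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[c] = v
            trials = pd.DataFrame(cols)
        if "ground_truth" in f:
            g = f["ground_truth"]
            truth = GroundTruth(
                movement_gain_map=g["movement_gain_map"][()],
                force_gain_map=g["force_gain_map"][()],
                latent_traces=g["latent_traces"][()],
                true_mode_labels=g["true_mode_labels"][()],
                true_onsets=pd.DataFrame(
                    {c: g["true_onsets"][c][()] for c in g["true_onsets"]}
                ),
                flexion=g["flexion"][()],
                lock_class=g["lock_class"][()],
            )
    return session, trials, truth
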