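"""Synthetic movement-force ECoG sessions with known ground truth.

The generator emulates the structure of a cued one-finger task in which a
subject holds still (premovement), executes a self-paced flexion movement,
and then presses an isometric force sensor to match a randomly drawn force
target, with a fixed inter-trial delay.  Each electrode's continuous signal
is a sum of two band-limited carriers (a broadband low-frequency component,
8-55 Hz, and a broadband high-frequency component, 70-150 Hz) whose
instantaneous amplitudes are modulated by

* smooth movement- and force-locked envelopes, weighted by two spatially
  smooth per-electrode gain maps whose peaks are planted a configurable
  distance apart, and
* a small number of smooth latent traces shared across electrodes,

plus optional white noise.  High-frequency amplitude increases with
movement/force; low-frequency amplitude decreases.  Amplitude modulation is
applied on the log scale, so the log band power of each electrode is (up to
spectral-estimation noise) a linear function of the planted envelopes and
latents -- which makes every downstream stage testable against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SessionData",
    "plant_gain_maps",
    "simulate_session",
    "simulate_latent_features",
    "separable_class_data",
]

#: band edges used by the generator's carriers (Hz)
LOW_BAND = (8.0, 55.0)
HIGH_BAND = (70.0, 150.0)

# per-sample mode codes in GroundTruth.true_mode_labels
MODE_UNLABELED, MODE_PREMOVE, MODE_MOVEMENT, MODE_FORCE = 0, 1, 2, 3


@dataclass
class SimulationConfig:
    """Parameters of one synthetic session.

    Durations are means of truncated normals (SD = the matching
    ``*_jitter_s``, floor ``min_mode_s``); the force-hold duration is fixed
    by default.  ``snr`` is the ratio of combined carrier RMS to additive
    white-noise RMS; ``numpy.inf`` disables the noise term.  ``lock_probs``
    are the probabilities that an electrode is movement-locked only,
    force-locked only, or locked to both.
    """

    n_trials: int = 60
    n_rows: int = 4
    n_cols: int = 4
    pitch_mm: float = 4.0
    fs_hz: float = 2000.0
    premove_s: float = 0.8
    move_s: float = 0.4
    force_s: float = 1.0
    premove_jitter_s: float = 0.15
    move_jitter_s: float = 0.15
    force_jitter_s: float = 0.0
    min_mode_s: float = 0.1
    iti_s: float = 1.0
    lead_in_s: float = 1.0
    planted_peak_shift_mm: float = 8.0
    latent_dim: int = 3
    snr: float = 5.0
    lock_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)
    carrier: str = "noise"  # "noise" (band-limited noise) or "multisine"
    mod_depth: float = 0.6
    # band mixing weights ((high<-movement, high<-force), (low<-movement,
    # low<-force)); the mirrored default makes movement and force
    # separable from one electrode's two bands and exchangeable under a
    # band swap, so the zero-shift case is a clean null
    band_mix: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.6), (0.6, 1.0))
    latent_gain: float = 0.25
    n_kin_sensors: int = 4
    kin_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("premove_s", "move_s", "force_s", "iti_s", "min_mode_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.carrier not in ("noise", "multisine"):
            raise ValueError("carrier must be 'noise' or 'multisine'")
        if not np.isclose(sum(self.lock_probs), 1.0):
            raise ValueError("lock_probs must sum to 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    movement_gain_map: np.ndarray  # (n_rows, n_cols), non-negative
    force_gain_map: np.ndarray  # (n_rows, n_cols), non-negative
    latent_traces: np.ndarray  # (latent_dim, n_samples)
    true_mode_labels: np.ndarray  # (n_samples,) int8 mode codes
    true_onsets: pd.DataFrame  # per trial: movement_onset_s, force_onset_s
    flexion: np.ndarray  # (n_samples,) noiseless kinematic trace
    lock_class: np.ndarray  # per electrode: 0 movement, 1 force, 2 both


@dataclass
class SessionData:
    """In-memory continuous recording plus behavior traces and geometry."""

    signal: np.ndarray  # (n_channels, n_samples)
    fs_hz: float
    channels: pd.DataFrame  # id, row, col, x_mm, y_mm, include
    kinematics: np.ndarray  # (n_sensors, n_samples)
    force: np.ndarray  # (n_samples,)
    cue_times_s: np.ndarray  # (n_trials,)
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def _achievable_shifts(n_rows: int, n_cols: int, pitch_mm: float) -> np.ndarray:
    dr = np.arange(-(n_rows - 1), n_rows)
    dc = np.arange(-(n_cols - 1), n_cols)
    dd = np.hypot(*np.meshgrid(dr * pitch_mm, dc * pitch_mm, indexing="ij"))
    return np.unique(np.round(dd.ravel(), 6))


def plant_gain_maps(
    n_rows: int,
    n_cols: int,
    pitch_mm: float,
    shift_mm: float,
    seed: int,
    sigma_sites: float = 1.3,
):
    """Two smooth unimodal gain maps with argmax peaks exactly ``shift_mm`` apart.

    Peaks sit on grid sites; the offset between them is drawn (seeded) from
    all integer grid offsets whose Euclidean length equals ``shift_mm``.
    Raises ``ValueError`` listing the achievable shifts when no offset
    matches or the grid cannot host both peaks.
    """
    rng = np.random.default_rng(seed)
    # integer offsets with the requested Euclidean length
    offs = [
        (dr, dc)
        for dr in range(-(n_rows - 1), n_rows)
        for dc in range(-(n_cols - 1), n_cols)
        if abs(np.hypot(dr, dc) * pitch_mm - shift_mm) < 1e-6
    ]
    if not offs:
        ach = _achievable_shifts(n_rows, n_cols, pitch_mm)
        raise ValueError(
            f"shift of {shift_mm} mm not representable on a {n_rows}x{n_cols} grid "
            f"with {pitch_mm} mm pitch; achievable shifts: {ach.tolist()}"
        )
    order = rng.permutation(len(offs))
    for k in order:
        dr, dc = offs[k]
        rows_ok = [r for r in range(n_rows) if 0 <= r + dr < n_rows]
        cols_ok = [c for c in range(n_cols) if 0 <= c + dc < n_cols]
        if rows_ok and cols_ok:
            r0 = rows_ok[len(rows_ok) // 2]
            c0 = cols_ok[len(cols_ok) // 2]
            r1, c1 = r0 + dr, c0 + dc
            break
    else:  # pragma: no cover - offsets always fit by construction
        raise ValueError("grid too small to place both planted peaks")

    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")

    def bump(r, c):
        m = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma_sites**2))
        m /= m.max()
        # truncate the far tail so distant electrodes carry exactly zero gain
        return np.clip((m - 0.1) / 0.9, 0.0, None)

    mov = bump(r0, c0)
    frc = bump(r1, c1)
    if shift_mm == 0 and (r0, c0) != (r1, c1):  # pragma: no cover
        raise AssertionError
    return mov, frc


def _trunc_normal(rng, mean, sd, floor, size):
    x = rng.normal(mean, sd, size)
    return np.maximum(x, floor)


def _raised_cosine_step(t, t0, width):
    """Smooth 0->1 step starting at t0, complete at t0+width."""
    x = np.clip((t - t0) / max(width, 1e-9), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def _band_carrier(rng, band, fs, n, kind):
    """Unit-RMS carrier confined to ``band``."""
    lo, hi = band
    if kind == "noise":
        w = rng.standard_normal(n)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, w)
    else:
        # deterministic multisine on harmonics of 40 Hz = 1 / (25-ms hop):
        # every analysis window placed on the default hop grid sees the
        # same waveform, so an unmodulated electrode yields constant
        # band-power features
        base = 40.0
        fb = np.arange(np.ceil(lo / base), np.floor(hi / base) + 1) * base
        if len(fb) == 0:  # pragma: no cover - default bands contain harmonics
            raise ValueError(f"band {band} contains no multisine harmonics")
        ph = rng.uniform(0, 2 * np.pi, len(fb))
        t = np.arange(n) / fs
        x = np.zeros(n)
        for f, p in zip(fb, ph):
            x += np.cos(2 * np.pi * f * t + p)
    return x / x.std()


def simulate_session(config: SimulationConfig):
    """Generate one session.

    Returns ``(session, trials, truth)`` where ``session`` is a
    :class:`SessionData`, ``trials`` a per-trial event table (the ground-truth
    trial table; the behavior module re-derives its own from the traces) and
    ``truth`` a :class:`GroundTruth`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_hz
    n_elec = cfg.n_rows * cfg.n_cols

    mov_map, frc_map = plant_gain_maps(
        cfg.n_rows, cfg.n_cols, cfg.pitch_mm, cfg.planted_peak_shift_mm,
        seed=rng.integers(2**31),
    )

    # --- trial event schedule -------------------------------------------
    pm = _trunc_normal(rng, cfg.premove_s, cfg.premove_jitter_s, cfg.min_mode_s, cfg.n_trials)
    mv = _trunc_normal(rng, cfg.move_s, cfg.move_jitter_s, cfg.min_mode_s, cfg.n_trials)
    fc = _trunc_normal(rng, cfg.force_s, cfg.force_jitter_s, cfg.min_mode_s, cfg.n_trials)
    targets = rng.uniform(0.2, 1.0, cfg.n_trials)
    move_amps = rng.uniform(0.2, 1.0, cfg.n_trials)  # self-paced excursion size

    cue = np.empty(cfg.n_trials)
    t_cursor = cfg.lead_in_s
    mo = np.empty(cfg.n_trials)
    fo = np.empty(cfg.n_trials)
    fend = np.empty(cfg.n_trials)
    for i in range(cfg.n_trials):
        cue[i] = t_cursor
        mo[i] = cue[i] + pm[i]
        fo[i] = mo[i] + mv[i]
        fend[i] = fo[i] + fc[i]
        t_cursor = fend[i] + cfg.iti_s
    total_s = fend[-1] + cfg.iti_s
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    # --- behavioral envelopes at sample resolution ----------------------
    flexion = np.zeros(n)
    force = np.zeros(n)
    labels = np.zeros(n, dtype=np.int8)
    peak_force_t = np.empty(cfg.n_trials)

    def add_pulse(buf, t_on, w_on, t_off, w_off, amp=1.0):
        # (step up at t_on) - (step up at t_off): nonzero only on a local span
        s0 = max(int((t_on - 0.01) * fs), 0)
        s1 = min(int((t_off + w_off + 0.01) * fs) + 1, n)
        tl = t[s0:s1]
        buf[s0:s1] += amp * (
            _raised_cosine_step(tl, t_on, w_on) - _raised_cosine_step(tl, t_off, w_off)
        )

    # The neural movement/force envelopes are the behavioral traces
    # themselves (flexion and force): this keeps the two modes statistically
    # exchangeable apart from the planted gain-map shift, so the zero-shift
    # configuration is a genuine null for the spatial-map comparison.
    for i in range(cfg.n_trials):
        # kinematics: rise across the movement period, hold during force
        add_pulse(flexion, mo[i], max(fo[i] - mo[i], 0.05), fend[i], 0.30,
                  amp=move_amps[i])
        # force trace: ramp to the trial's random target after contact
        add_pulse(force, fo[i], 0.30, fend[i], 0.30, amp=targets[i])
        peak_force_t[i] = 0.5 * (fo[i] + 0.30 + fend[i])  # mid-plateau
        s = slice(int(cue[i] * fs), min(int(mo[i] * fs), n))  # noqa: E741
        labels[s] = MODE_PREMOVE
        s = slice(int(mo[i] * fs), min(int(fo[i] * fs), n))
        labels[s] = MODE_MOVEMENT
        s = slice(int(fo[i] * fs), min(int((fo[i] + 0.5) * fs), n))
        labels[s] = MODE_FORCE

    # --- latent traces (smooth, unit variance, shared across electrodes) -
    # drawn at 100 Hz, Gaussian-smoothed (0.2 s), linearly upsampled to fs
    fs_lat = 100.0
    n_lat = int(np.ceil(n / fs * fs_lat)) + 2
    lat = rng.standard_normal((cfg.latent_dim, n_lat))
    lat = gaussian_filter1d(lat, sigma=0.2 * fs_lat, axis=1, mode="reflect")
    t_lat = np.arange(n_lat) / fs_lat
    lat = np.stack([np.interp(t, t_lat, row) for row in lat])
    lat = (lat - lat.mean(axis=1, keepdims=True)) / lat.std(axis=1, keepdims=True)

    # --- per-electrode modulation ---------------------------------------
    lock = rng.choice(3, size=n_elec, p=cfg.lock_probs)  # 0 mov, 1 force, 2 both
    lock_m = (lock != 1).astype(float)
    lock_f = (lock != 0).astype(float)
    g_m = mov_map.ravel()
    g_f = frc_map.ravel()
    g_tot = np.maximum(g_m, g_f)
    loadings = rng.standard_normal((n_elec, cfg.latent_dim))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    loadings *= g_tot[:, None]

    base_lo, base_hi = 1.0, 0.5
    sig = np.empty((n_elec, n))
    noise_sd = 0.0 if np.isinf(cfg.snr) else (base_lo + base_hi) / cfg.snr
    (hm, hf), (lm, lf) = cfg.band_mix
    for e in range(n_elec):
        drive_m = cfg.mod_depth * lock_m[e] * g_m[e] * flexion
        drive_f = cfg.mod_depth * lock_f[e] * g_f[e] * force
        lat_e = cfg.latent_gain * (loadings[e] @ lat)
        a_hi = base_hi * np.exp(hm * drive_m + hf * drive_f + lat_e)
        a_lo = base_lo * np.exp(-(lm * drive_m + lf * drive_f) - lat_e)
        c_lo = _band_carrier(rng, LOW_BAND, fs, n, cfg.carrier)
        c_hi = _band_carrier(rng, HIGH_BAND, fs, n, cfg.carrier)
        sig[e] = a_lo * c_lo + a_hi * c_hi
        if noise_sd > 0:
            sig[e] += noise_sd * rng.standard_normal(n)

    # --- glove-like sensors ---------------------------------------------
    gains = rng.uniform(0.8, 1.2, cfg.n_kin_sensors)
    kin = gains[:, None] * flexion[None, :]
    if cfg.kin_noise > 0:
        kin = kin + cfg.kin_noise * rng.standard_normal(kin.shape)

    rows, cols = np.divmod(np.arange(n_elec), cfg.n_cols)
    channels = pd.DataFrame(
        {
            "id": np.arange(n_elec),
            "row": rows,
            "col": cols,
            "x_mm": cols * cfg.pitch_mm,
            "y_mm": rows * cfg.pitch_mm,
            "include": np.ones(n_elec, dtype=bool),
        }
    )
    session = SessionData(
        signal=sig,
        fs_hz=fs,
        channels=channels,
        kinematics=kin,
        force=force,
        cue_times_s=cue,
        provenance={"seed": cfg.seed, "config": dataclasses.asdict(cfg)},
    )
    trials = pd.DataFrame(
        {
            "cue_time_s": cue,
            "movement_onset_s": mo,
            "force_onset_s": fo,
            "force_end_s": fend,
            "peak_force_time_s": peak_force_t,
            "force_target": targets,
            "outcome": "matched",
            "valid": True,
        }
    )
    truth = GroundTruth(
        movement_gain_map=mov_map,
        force_gain_map=frc_map,
        latent_traces=lat,
        true_mode_labels=labels,
        true_onsets=trials[["movement_onset_s", "force_onset_s"]].copy(),
        flexion=flexion,
        lock_class=lock,
    )
    return session, trials, truth


def simulate_latent_features(
    n_trials: int = 60,
    n_features: int = 40,
    latent_dim: int = 3,
    n_bins: int = 50,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Linear-Gaussian benchmark for the latent-dynamics model.

    Latents follow a damped-rotation linear dynamical system with random
    per-trial initial conditions; observations are a fixed linear readout
    plus white Gaussian noise, z-scored per feature.  Returns
    ``(x, z)`` with ``x`` of shape (trials, bins, features) and ``z`` the
    true latents (trials, bins, latent_dim).
    """
    rng = np.random.default_rng(seed)
    # block-diagonal damped rotations -> smooth quasi-periodic latents
    A = np.zeros((latent_dim, latent_dim))
    i = 0
    while i + 1 < latent_dim:
        th = rng.uniform(0.05, 0.25)
        damp = rng.uniform(0.97, 0.995)
        A[i : i + 2, i : i + 2] = damp * np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        )
        i += 2
    if i < latent_dim:
        A[i, i] = rng.uniform(0.95, 0.99)
    z = np.empty((n_trials, n_bins, latent_dim))
    z0 = rng.standard_normal((n_trials, latent_dim))
    z[:, 0] = z0
    for tt in range(1, n_bins):
        z[:, tt] = z[:, tt - 1] @ A.T
    z /= z.reshape(-1, latent_dim).std(axis=0)
    W = rng.standard_normal((latent_dim, n_features))
    x = z @ W + noise_sd * rng.standard_normal((n_trials, n_bins, n_features))
    flat = x.reshape(-1, n_features)
    x = (x - flat.mean(0)) / flat.std(0)
    return x, z


def separable_class_data(
    n_trials: int = 60,
    bins_per_mode: tuple[int, int, int] = (12, 8, 20),
    n_features: int = 20,
    separation: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Trial-structured bins with class-specific feature means.

    Used to exercise mode classification on a case with known separability:
    each trial contributes contiguous premovement/movement/force blocks whose
    feature vectors sit at three distinct means ``separation`` apart.
    Returns ``(X, labels, trial_ids)``; labels use the generator mode codes.
    """
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((3, n_features))
    means *= separation / np.linalg.norm(means, axis=1, keepdims=True)
    X, y, tid = [], [], []
    for tr in range(n_trials):
        for mode, nb in enumerate(bins_per_mode):
            X.append(means[mode] + noise_sd * rng.standard_normal((nb, n_features)))
            y.extend([mode + 1] * nb)  # codes 1,2,3
            tid.extend([tr] * nb)
    return np.vstack(X), np.asarray(y, dtype=np.int8), np.asarray(tid)
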