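"""Band-power feature extraction and the lagged decoding design matrix.

The continuous multichannel signal is cut into 256-ms Hanning-windowed
segments hopped by 25 ms (231 ms overlap).  For every segment and channel
the FFT power spectrum is computed, log-transformed, and normalized per
channel and frequency bin by subtracting the session-mean log power (the
log of the geometric mean power over the whole record), so a stationary
channel yields zero-mean features.  A band feature is the mean of the
normalized values over the frequency bins whose centers fall inside the
band; the defaults are a broadband low-frequency band (8-55 Hz) and a
broadband high-frequency band (70-150 Hz).  At 2 kHz and 256 ms the
frequency resolution is 2000/512 = 3.90625 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import hann

__all__ = [
    "BandDefinition",
    "FeatureTensor",
    "LaggedDesign",
    "DEFAULT_BANDS",
    "compute_band_features",
    "spectrogram_power",
    "build_lagged_design",
    "event_aligned_raster",
]

_LOG_EPS = 1e-12  # guard before log for silent channels


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def validate(self, fs_hz: float) -> None:
        if not (0 < self.lo_hz < self.hi_hz < fs_hz / 2):
            raise ValueError(
                f"band {self.name} ({self.lo_hz}-{self.hi_hz} Hz) must satisfy "
                f"0 < lo < hi < fs/2 = {fs_hz / 2}"
            )


DEFAULT_BANDS = (
    BandDefinition("low", 8.0, 55.0),
    BandDefinition("high", 70.0, 150.0),
)


@dataclass
class FeatureTensor:
    """Band-power features: one row per 25-ms bin, columns electrode-major
    then band (e0-low, e0-high, e1-low, ...)."""

    values: np.ndarray  # (n_bins, n_features)
    bin_times: np.ndarray  # window-center times, s
    window_s: float
    step_s: float
    feature_index: list[tuple[int, str]]  # (electrode id, band name) per column

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns_for_band(self, band: str) -> np.ndarray:
        return np.array([j for j, (_, b) in enumerate(self.feature_index) if b == band])

    def columns_for_electrode(self, elec: int) -> np.ndarray:
        return np.array([j for j, (e, _) in enumerate(self.feature_index) if e == elec])


@dataclass
class LaggedDesign:
    """Causal lagged design: row t concatenates feature rows t..t-n_lags+1."""

    values: np.ndarray  # (n_rows, n_features * n_lags)
    bin_times: np.ndarray
    n_lags: int


def _frame_indices(n_samples: int, win: int, hop: int) -> np.ndarray:
    n_bins = (n_samples - win) // hop + 1
    if n_bins < 1:
        raise ValueError("record shorter than one analysis window")
    return np.arange(n_bins) * hop


def spectrogram_power(
    x: np.ndarray,
    fs_hz: float,
    window_s: float = 0.256,
    step_s: float = 0.025,
    out_dtype=np.float64,
):
    """Hanning-windowed one-sided power spectral density per segment.

    Returns ``(psd, freqs, bin_times)`` where ``psd`` has shape
    (n_bins, n_freqs) and is scaled so that ``sum(psd, axis=1) * df``
    approximates the signal variance (Welch scaling).  This unnormalized
    path exists so band power can be checked against a direct
    filter-then-variance computation.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x.ravel()))[0]
        raise ValueError(f"non-finite sample at flat index {bad}")
    win = int(round(window_s * fs_hz))
    hop = int(round(step_s * fs_hz))
    starts = _frame_indices(x.shape[-1], win, hop)
    # single precision for the FFT stage: ample for log-power features and
    # much faster on SIMD units; accumulate back in double
    freqs, _, psd = sps.spectrogram(
        x.astype(np.float32),
        fs=fs_hz,
        window=hann(win, sym=False).astype(np.float32),
        nperseg=win,
        noverlap=win - hop,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    psd = np.moveaxis(psd, -1, -2)  # (..., n_bins, n_freqs), float32
    if out_dtype is not None:
        psd = psd.astype(out_dtype)
    bin_times = (starts + win / 2.0) / fs_hz
    return psd, freqs, bin_times


def compute_band_features(
    session,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: float = 0.256,
    step_s: float = 0.025,
    normalize: bool = True,
) -> FeatureTensor:
    """Per-electrode, per-band normalized log power in 25-ms bins.

    ``session`` is any object with ``signal`` (channels x samples) and
    ``fs_hz``.  Only channels flagged ``include`` in ``session.channels``
    are used when that table is present.
    """
    fs = session.fs_hz
    for b in bands:
        b.validate(fs)
    sig = np.asarray(session.signal, dtype=float)
    chan_ids = np.arange(sig.shape[0])
    channels = getattr(session, "channels", None)
    if channels is not None and "include" in channels:
        keep = channels["include"].to_numpy().astype(bool)
        chan_ids = channels["id"].to_numpy()[keep]
        sig = sig[keep]

    psd, freqs, bin_times = spectrogram_power(sig, fs, window_s, step_s, out_dtype=None)
    band_masks = []
    union = np.zeros(len(freqs), dtype=bool)
    for b in bands:
        m = (freqs >= b.lo_hz) & (freqs <= b.hi_hz)
        if not m.any():
            raise ValueError(f"band {b.name} contains no resolvable frequency bins")
        band_masks.append(m)
        union |= m
    # only in-band frequency bins enter the features; skip the rest
    logp = np.log(psd[..., union].astype(np.float64) + _LOG_EPS)
    if normalize:
        logp = logp - logp.mean(axis=1, keepdims=True)  # per channel+freq bin

    cols = []
    index: list[tuple[int, str]] = []
    for ci, cid in enumerate(chan_ids):
        for b, m in zip(bands, band_masks):
            cols.append(logp[ci][:, m[union]].mean(axis=1))
            index.append((int(cid), b.name))
    values = np.stack(cols, axis=1)
    return FeatureTensor(values, bin_times, window_s, step_s, index)


def build_lagged_design(features: FeatureTensor, n_lags: int = 10) -> LaggedDesign:
    """Concatenate the current bin with ``n_lags - 1`` causal history bins.

    Rows with incomplete history are dropped, so the design has
    ``n_bins - n_lags + 1`` rows and ``n_features * n_lags`` columns with
    lag-major blocks [t, t-1, ..., t-n_lags+1].
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    v = features.values
    if n_lags > v.shape[0]:
        raise ValueError(f"n_lags={n_lags} exceeds available bins ({v.shape[0]})")
    blocks = [v[n_lags - 1 - k : v.shape[0] - k] for k in range(n_lags)]
    return LaggedDesign(
        values=np.concatenate(blocks, axis=1),
        bin_times=features.bin_times[n_lags - 1 :],
        n_lags=n_lags,
    )


def event_aligned_raster(
    features: FeatureTensor,
    column: int,
    event_times: np.ndarray,
    pre_s: float,
    post_s: float,
    sort_key: np.ndarray | None = None,
):
    """Single-feature intensity raster: trials x peri-event bins, z-scored.

    The feature column is z-scored over the whole session (zero-variance
    columns map to zeros), then windowed around each event.  Events whose
    window falls outside the record are dropped with a warning.  Rows are
    ordered by ``sort_key`` when given (e.g. elapsed time between events).
    Returns ``(raster, rel_times, kept)`` with ``kept`` the indices of the
    retained events in row order.
    """
    import warnings

    x = features.values[:, column]
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    step = features.step_s
    n_pre = int(round(pre_s / step))
    n_post = int(round(post_s / step))
    rel = np.arange(-n_pre, n_post + 1) * step
    rows, kept = [], []
    for i, ev in enumerate(np.asarray(event_times, dtype=float)):
        c = int(np.argmin(np.abs(features.bin_times - ev)))
        if c - n_pre < 0 or c + n_post >= features.n_bins:
            warnings.warn(f"event {i} at {ev:.3f}s too close to record edge; excluded")
            continue
        rows.append(z[c - n_pre : c + n_post + 1])
        kept.append(i)
    if not rows:
        raise ValueError("no events with a full peri-event window")
    raster = np.stack(rows)
    kept = np.asarray(kept)
    if sort_key is not None:
        order = np.argsort(np.asarray(sort_key)[kept], kind="stable")
        raster = raster[order]
        kept = kept[order]
    return raster, rel, kept
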