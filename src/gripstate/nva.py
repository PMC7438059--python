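"""Neural vector angle (NVA): angular distance of the feature vector from
its value near peak force.

Features are first grouped by k-means on their trial-averaged peri-event
time courses; of the resulting clusters the two with the deepest
modulation (peak-to-trough of the cluster-mean trace) are kept and tagged
low/high by the majority band of their members.  Per trial, the selected
features form a vector m(t), smoothed with a centered 5-bin (125 ms)
boxcar; the reference m_ref is the mean of m over the 250 ms before the
trial's peak-force time, and

    theta(t) = arccos( m(t) . m_ref / (||m(t)|| ||m_ref||) )   [degrees]

Angles live in [0, 180] degrees, which makes them comparable (and
averageable) across trials, sessions, and subjects.  Mode differences are
tested with a Kruskal-Wallis test plus Tukey HSD on ranks post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .behavior import FORCE, MOVEMENT, PREMOVEMENT

__all__ = [
    "FeatureClustering",
    "NVAResult",
    "select_feature_clusters",
    "neural_vector_angle",
    "nva_time_course",
    "compare_modes_nva",
    "trial_averaged_traces",
]

_NORM_EPS = 1e-9


@dataclass
class FeatureClustering:
    labels: np.ndarray  # cluster id per feature
    k: int
    silhouette: np.ndarray  # per feature
    selected: dict = field(default_factory=dict)  # tag ("low"/"high") -> cluster id

    def features_in(self, tag: str) -> np.ndarray:
        return np.flatnonzero(self.labels == self.selected[tag])


def trial_averaged_traces(
    features, trials, align: str = "force_onset_s",
    pre_s: float = 1.5, post_s: float = 0.75, zscore: bool = True,
):
    """Per-feature trial-averaged peri-event traces, (features, bins)."""
    from .lfads import trial_feature_windows

    win = trial_feature_windows(features, trials, band=None, align=align,
                                pre_s=pre_s, post_s=post_s)
    avg = win.values.mean(axis=0).T  # (features, bins)
    if not zscore:
        # undo the session z-scoring applied by the window builder
        sd = features.values.std(axis=0)
        sd[sd == 0] = 1.0
        avg = avg * sd[:, None] + features.values.mean(axis=0)[:, None]
    return avg, win.rel_times


def select_feature_clusters(
    trial_avg: np.ndarray,
    feature_bands: list[str],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 20,
    max_reseeds: int = 10,
) -> FeatureClustering:
    """K-means over trial-averaged feature traces; keep the two most
    modulated clusters, tagged low/high by majority band membership."""
    X = np.asarray(trial_avg, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} features, got {X.shape[0]}")
    if not (2 <= k <= 5):
        raise ValueError("k must be in [2, 5]")
    labels = None
    for attempt in range(max_reseeds):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + attempt)
        cand = km.fit_predict(X)
        if len(np.unique(cand)) == k:
            labels = cand
            break
    if labels is None:
        raise RuntimeError(f"k-means produced an empty cluster in {max_reseeds} restarts")
    sil = silhouette_samples(X, labels)
    depth = np.array([np.ptp(X[labels == c].mean(axis=0)) for c in range(k)])
    top2 = np.argsort(depth)[::-1][:2]
    bands = np.asarray(feature_bands)
    low_frac = [np.mean(bands[labels == c] == "low") for c in top2]
    # the cluster with the larger low-band share is "low"; the other "high"
    if low_frac[0] >= low_frac[1]:
        selected = {"low": int(top2[0]), "high": int(top2[1])}
    else:
        selected = {"low": int(top2[1]), "high": int(top2[0])}
    return FeatureClustering(labels=labels, k=k, silhouette=sil, selected=selected)


def neural_vector_angle(m_t: np.ndarray, m_ref: np.ndarray, eps: float = _NORM_EPS):
    """Angle in degrees between feature vector(s) and the reference.

    ``m_t`` may be a single vector or (bins, dim); bins whose norm (or the
    reference's norm) falls below ``eps`` return NaN (undefined direction).
    """
    m = np.atleast_2d(np.asarray(m_t, dtype=float))
    r = np.asarray(m_ref, dtype=float)
    if m.shape[1] != r.shape[0]:
        raise ValueError("dimension mismatch between m(t) and reference")
    nm = np.linalg.norm(m, axis=1)
    nr = np.linalg.norm(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (m @ r) / (nm * nr)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta[nm <= eps] = np.nan
    if nr <= eps:
        theta[:] = np.nan
    out = theta if np.ndim(m_t) > 1 else float(theta[0])
    return out


def _smooth_boxcar(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average along axis 0 with edge truncation."""
    if width <= 1:
        return x
    kernel = np.ones(width)
    num = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, x)
    den = np.convolve(np.ones(x.shape[0]), kernel, mode="same")
    return num / den[:, None]


@dataclass
class NVAResult:
    theta: dict  # tag -> (trials, bins) angles in degrees
    rel_times: np.ndarray  # peri-event bin times, s (relative to alignment)
    trial_index: np.ndarray  # rows of the trial table used
    align: str


def nva_time_course(
    features,
    clustering: FeatureClustering,
    trials: pd.DataFrame,
    align: str = "force_onset_s",
    pre_s: float = 1.5,
    post_s: float = 0.75,
    smooth_bins: int = 5,
    ref_s: float = 0.25,
) -> NVAResult:
    """Per-trial NVA time courses for each selected feature cluster.

    m(t) is smoothed with a centered ``smooth_bins`` boxcar (125 ms at
    25-ms bins); m_ref averages the smoothed m over [peak_force - ref_s,
    peak_force).  Trials whose peri-event or reference window leaves the
    record are skipped with a warning.
    """
    import warnings

    step = features.step_s
    n_pre = int(round(pre_s / step))
    n_post = int(round(post_s / step))
    rel = np.arange(-n_pre, n_post) * step
    n_ref = max(int(round(ref_s / step)), 1)

    sm = _smooth_boxcar(features.values, smooth_bins)
    tt = trials[trials["valid"]] if "valid" in trials else trials
    theta = {tag: [] for tag in clustering.selected}
    used = []
    for ti, tr in tt.iterrows():
        ev = tr[align]
        pk = tr["peak_force_time_s"]
        c = int(np.argmin(np.abs(features.bin_times - ev)))
        pkc = int(np.argmin(np.abs(features.bin_times - pk)))
        if c - n_pre < 0 or c + n_post > features.n_bins or pkc - n_ref < 0:
            warnings.warn(f"trial {ti}: window outside record; skipped")
            continue
        used.append(ti)
        for tag in clustering.selected:
            cols = clustering.features_in(tag)
            m = sm[:, cols]
            m_ref = m[pkc - n_ref : pkc].mean(axis=0)
            theta[tag].append(neural_vector_angle(m[c - n_pre : c + n_post], m_ref))
    if not used:
        raise ValueError("no trials with complete NVA windows")
    return NVAResult(
        theta={tag: np.stack(v) for tag, v in theta.items()},
        rel_times=rel,
        trial_index=np.asarray(used),
        align=align,
    )


def mode_of_peri_event_bins(result: NVAResult, trials: pd.DataFrame) -> dict:
    """Mode code per (trial, peri-event bin) derived from the trial table."""
    modes = np.zeros((len(result.trial_index), len(result.rel_times)), dtype=np.int8)
    for i, ti in enumerate(result.trial_index):
        tr = trials.loc[ti]
        t_abs = tr[result.align] + result.rel_times
        modes[i][(t_abs >= tr["cue_time_s"]) & (t_abs < tr["movement_onset_s"])] = PREMOVEMENT
        modes[i][(t_abs >= tr["movement_onset_s"]) & (t_abs < tr["force_onset_s"])] = MOVEMENT
        modes[i][(t_abs >= tr["force_onset_s"]) & (t_abs < tr["force_onset_s"] + 0.5)] = FORCE
    return modes


def compare_modes_nva(
    result: NVAResult,
    trials: pd.DataFrame,
    tag: str | None = None,
    min_per_mode: int = 5,
) -> dict:
    """Kruskal-Wallis across mode-wise NVA samples, Tukey HSD on ranks post hoc.

    Angles from all trials are pooled by the behavioral mode of their bin.
    Returns a dict with the H statistic, p-value, per-mode medians and
    sample sizes, the post hoc p-value matrix, and a ``flags`` list noting
    degenerate situations (e.g. a missing mode).
    """
    tags = [tag] if tag else list(result.theta)
    out = {}
    for tg in tags:
        th = result.theta[tg]
        modes = mode_of_peri_event_bins(result, trials)
        samples, names = [], []
        flags = []
        for code, name in ((PREMOVEMENT, "premovement"), (MOVEMENT, "movement"), (FORCE, "force")):
            vals = th[modes == code]
            vals = vals[np.isfinite(vals)]
            if len(vals) >= min_per_mode:
                samples.append(vals)
                names.append(name)
            else:
                flags.append(f"mode {name} has <{min_per_mode} samples; excluded")
        if len(samples) < 2:
            raise ValueError("need at least two modes with enough samples")
        h, p = stats.kruskal(*samples)
        ranks = stats.rankdata(np.concatenate(samples))
        split = np.split(ranks, np.cumsum([len(s) for s in samples])[:-1])
        posthoc = stats.tukey_hsd(*split)
        out[tg] = {
            "H": float(h),
            "p": float(p),
            "modes": names,
            "medians": {n: float(np.median(s)) for n, s in zip(names, samples)},
            "n": {n: int(len(s)) for n, s in zip(names, samples)},
            "posthoc_p": posthoc.pvalue.tolist(),
            "flags": flags,
        }
    return out if tag is None else out[tag]
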