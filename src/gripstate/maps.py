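"""Single-electrode decoding maps and their spatial comparison.

A decoding map assigns each electrode of the grid its cross-validated FVAF
when it alone (two band features x lag history) drives a Wiener-cascade
decoder; one map per fold and behavioral mode.  Two summary statistics
compare movement and force maps: the Euclidean displacement of the peak
site in millimetres, and the normalized map distance

    D(a, b) = || clip(a,0,1) - clip(b,0,1) || / sqrt(n_electrodes),

which lies in [0, 1] because each clipped electrode value differs by at
most 1.  Cross-mode distances (D_inter) are tested one-tailed against
within-mode distances (D_intra) with a Wilcoxon signed-rank test, pairing
each cross-mode fold pair (i, j) with the mean of the two within-mode
distances for those folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decoding import DEFAULT_LAMBDAS, crossval_decode
from .features import FeatureTensor, build_lagged_design

__all__ = [
    "DecodingMap",
    "MapComparison",
    "single_electrode_maps",
    "peak_displacement",
    "map_distance",
    "compare_inter_intra",
]


@dataclass
class DecodingMap:
    """Per-electrode test-fold FVAF with grid coordinates in mm."""

    fvaf: np.ndarray  # (n_electrodes,)
    coords_mm: np.ndarray  # (n_electrodes, 2)
    mode: str  # "movement" or "force"
    fold: int

    def clipped(self) -> np.ndarray:
        return np.clip(self.fvaf, 0.0, 1.0)


def single_electrode_maps(
    features: FeatureTensor,
    target: np.ndarray,
    coords_mm: np.ndarray,
    mode: str,
    n_folds: int = 10,
    n_lags: int = 10,
    lambdas=DEFAULT_LAMBDAS,
) -> list[DecodingMap]:
    """One decoding map per fold, built electrode by electrode.

    ``target`` must align with the lagged design's rows, i.e. have length
    ``features.n_bins - n_lags + 1`` (or ``features.n_bins``, in which case
    the first ``n_lags - 1`` samples are dropped to match).
    """
    electrodes = sorted({e for e, _ in features.feature_index})
    y = np.asarray(target, dtype=float)
    if y.shape[0] == features.n_bins:
        y = y[n_lags - 1 :]
    maps_by_fold = None
    coords = np.asarray(coords_mm, dtype=float)
    if coords.shape[0] != len(electrodes):
        raise ValueError("coords_mm rows must match the electrode count")
    for ei, elec in enumerate(electrodes):
        cols = features.columns_for_electrode(elec)
        sub = FeatureTensor(
            features.values[:, cols],
            features.bin_times,
            features.window_s,
            features.step_s,
            [features.feature_index[c] for c in cols],
        )
        design = build_lagged_design(sub, n_lags)
        try:
            cv = crossval_decode(design, y, n_folds=n_folds, lambdas=lambdas)
            vals = cv.fold_fvaf
        except (ValueError, np.linalg.LinAlgError):
            vals = np.full(n_folds, np.nan)  # site marked missing
        if maps_by_fold is None:
            maps_by_fold = np.empty((n_folds, len(electrodes)))
        maps_by_fold[:, ei] = vals
    return [
        DecodingMap(fvaf=maps_by_fold[f], coords_mm=coords, mode=mode, fold=f)
        for f in range(n_folds)
    ]


def peak_displacement(map_a: DecodingMap, map_b: DecodingMap) -> float:
    """Euclidean distance (mm) between the two maps' argmax sites.

    Argmax ties break to the first (row-major) occurrence.  NaN sites are
    ignored; an all-NaN map raises.
    """
    if map_a.coords_mm.shape != map_b.coords_mm.shape or not np.allclose(
        map_a.coords_mm, map_b.coords_mm
    ):
        raise ValueError("maps are on different grids")
    out = []
    for m in (map_a, map_b):
        v = m.fvaf
        if np.all(np.isnan(v)):
            raise ValueError("map has no valid sites")
        out.append(m.coords_mm[np.nanargmax(v)])
    return float(np.linalg.norm(out[0] - out[1]))


def map_distance(map_a: DecodingMap, map_b: DecodingMap) -> float:
    """Normalized Euclidean distance between two maps, in [0, 1]."""
    a, b = map_a.clipped(), map_b.clipped()
    if a.shape != b.shape:
        raise ValueError("maps cover different electrode sets")
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise ValueError("maps share no valid electrodes")
    return float(np.linalg.norm(a[ok] - b[ok]) / np.sqrt(ok.sum()))


@dataclass
class MapComparison:
    d_inter: np.ndarray  # all cross-mode fold-pair distances
    d_intra_mvt: np.ndarray
    d_intra_force: np.ndarray
    displacements_mm: np.ndarray  # per fold pair (i, j)
    statistic: float
    p_value: float  # Bonferroni-adjusted, one-tailed
    p_value_raw: float

    @property
    def median_inter(self) -> float:
        return float(np.median(self.d_inter))

    @property
    def median_intra(self) -> float:
        return float(np.median(np.concatenate([self.d_intra_mvt, self.d_intra_force])))


def compare_inter_intra(
    maps_mvt: list[DecodingMap],
    maps_force: list[DecodingMap],
    bonferroni: int = 1,
) -> MapComparison:
    """Test whether cross-mode map distances exceed within-mode distances.

    Folds present in both mode lists are paired by index.  The paired,
    one-tailed Wilcoxon signed-rank statistic compares, over unordered fold
    pairs i < j, the mean cross-mode distance (D(m_i, f_j) + D(m_j, f_i))/2
    against the mean within-mode distance (D(m_i, m_j) + D(f_i, f_j))/2.
    """
    folds = sorted(
        {m.fold for m in maps_mvt} & {m.fold for m in maps_force}
    )
    if len(folds) < 3:
        raise ValueError("need at least 3 folds per mode")
    mv = {m.fold: m for m in maps_mvt}
    fr = {m.fold: m for m in maps_force}

    d_inter = np.array(
        [map_distance(mv[i], fr[j]) for i in folds for j in folds]
    )
    pairs = [(i, j) for a, i in enumerate(folds) for j in folds[a + 1 :]]
    d_intra_m = np.array([map_distance(mv[i], mv[j]) for i, j in pairs])
    d_intra_f = np.array([map_distance(fr[i], fr[j]) for i, j in pairs])
    inter_paired = np.array(
        [(map_distance(mv[i], fr[j]) + map_distance(mv[j], fr[i])) / 2 for i, j in pairs]
    )
    control = (d_intra_m + d_intra_f) / 2
    diffs = inter_paired - control
    if np.allclose(diffs, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(inter_paired, control, alternative="greater")
    disp = np.array([peak_displacement(mv[i], fr[j]) for i, j in pairs])
    return MapComparison(
        d_inter=d_inter,
        d_intra_mvt=d_intra_m,
        d_intra_force=d_intra_f,
        displacements_mm=disp,
        statistic=float(stat),
        p_value=float(min(p * bonferroni, 1.0)),
        p_value_raw=float(p),
    )
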