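"""Continuous decoding with a ridge-regularized Wiener cascade.

The decoder is a linear filter over the lagged band-power design matrix
followed by a static third-order polynomial nonlinearity fit to the linear
stage's training output.  Accuracy is the fractional variance accounted for
(FVAF = 1 - SSE/SST), evaluated with 11-fold cross-validation over
contiguous time blocks: per test fold, the ridge strength is chosen on a
separate validation fold, the model is refit on the nine training folds,
and FVAF is computed on the held-out fold.  Contiguous blocks (rather than
shuffled bins) are used because neighbouring lagged rows share samples and
interleaved folds would leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WienerCascadeModel",
    "CVResult",
    "fvaf",
    "fit_wiener_cascade",
    "crossval_decode",
    "sample_trace_at_bins",
    "DEFAULT_LAMBDAS",
]

#: logarithmic ridge grid searched on the validation fold
DEFAULT_LAMBDAS = np.logspace(-4, 4, 9)


def fvaf(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Fractional variance accounted for: 1 - SSE/SST.

    Equals 1 for a perfect prediction, 0 for predicting the mean of
    ``actual``, and is negative (unbounded below) for worse predictions.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or a.size < 2:
        raise ValueError("predicted and actual must share a length >= 2")
    sst = np.sum((a - a.mean()) ** 2)
    if sst == 0:
        raise ValueError("actual trace is constant; FVAF undefined")
    return float(1.0 - np.sum((a - p) ** 2) / sst)


@dataclass
class WienerCascadeModel:
    linear_weights: np.ndarray  # (M,)
    intercept: float
    poly_coeffs: np.ndarray  # (4,) ascending powers of the standardized linear output
    ridge_lambda: float
    lin_center: float = 0.0  # standardization of the linear stage's training output
    lin_scale: float = 1.0

    def linear_output(self, X: np.ndarray) -> np.ndarray:
        return X @ self.linear_weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        v = (self.linear_output(X) - self.lin_center) / self.lin_scale
        c = self.poly_coeffs
        return c[0] + v * (c[1] + v * (c[2] + v * c[3]))  # Horner


def _ridge_solve(Gc, bc, lam):
    return np.linalg.solve(Gc + lam * np.eye(Gc.shape[0]), bc)


def _fit_poly(lin: np.ndarray, y: np.ndarray):
    """Least-squares cubic of y on the standardized linear output.

    Returns ``(coeffs, center, scale)``; a near-constant linear output
    degenerates to predicting the training mean.
    """
    mu, sd = lin.mean(), lin.std()
    if sd < 1e-9 * (1.0 + np.abs(mu)):
        return np.array([float(np.mean(y)), 0.0, 0.0, 0.0]), float(mu), 1.0
    z = (lin - mu) / sd
    V = np.empty((len(z), 4))
    V[:, 0] = 1.0
    V[:, 1] = z
    V[:, 2] = z * z
    V[:, 3] = V[:, 2] * z
    cz, *_ = np.linalg.lstsq(V, y, rcond=None)
    return cz, float(mu), float(sd)


def fit_wiener_cascade(X: np.ndarray, y: np.ndarray, ridge_lambda: float = 0.0):
    """Fit the two-stage cascade on (design rows, target samples)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D design with at least 2 rows")
    if X.shape[0] != y.shape[0]:
        raise ValueError("design rows and target length differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target values")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    Gc = Xc.T @ Xc
    bc = Xc.T @ (y - ym)
    w = _ridge_solve(Gc, bc, ridge_lambda)
    b = ym - xm @ w
    lin = X @ w + b
    poly, c0, sc = _fit_poly(lin, y)
    return WienerCascadeModel(w, float(b), poly, float(ridge_lambda), c0, sc)


@dataclass
class CVResult:
    fold_fvaf: np.ndarray  # test-fold FVAF, one per fold
    chosen_lambda: np.ndarray  # per fold
    fold_bounds: list[tuple[int, int]] = field(default_factory=list)
    predictions: list[np.ndarray] = field(default_factory=list)  # per test fold

    @property
    def median(self) -> float:
        return float(np.median(self.fold_fvaf))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.fold_fvaf, [25, 75])
        return float(q3 - q1)


def crossval_decode(
    design,
    target: np.ndarray,
    n_folds: int = 11,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    min_bins_per_fold: int = 20,
) -> CVResult:
    """Blocked cross-validated Wiener-cascade decoding.

    ``design`` is a :class:`~gripstate.features.LaggedDesign` or a plain
    (rows x M) array whose rows align with ``target``.  Folds are contiguous
    equal blocks; for test fold i the validation fold is the next block
    (cyclically), training is the remaining ``n_folds - 2`` blocks.  The
    ridge strength is chosen per fold on the validation fold (ties broken
    toward the smallest lambda), the cascade refit on the training blocks,
    and FVAF reported on the test block.
    """
    X = design.values if hasattr(design, "values") else np.asarray(design, float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design rows and target length differ")
    n = X.shape[0]
    if n < n_folds * min_bins_per_fold:
        raise ValueError(
            f"need at least {n_folds * min_bins_per_fold} bins for "
            f"{n_folds}-fold cross-validation; got {n}"
        )
    fold_idx = np.array_split(np.arange(n), n_folds)
    bounds = [(int(f[0]), int(f[-1]) + 1) for f in fold_idx]

    # per-fold sufficient statistics of the linear stage
    M = X.shape[1]
    G = np.empty((n_folds, M, M))
    b = np.empty((n_folds, M))
    sx = np.empty((n_folds, M))
    sy = np.empty(n_folds)
    cnt = np.empty(n_folds)
    for f, idx in enumerate(fold_idx):
        Xf, yf = X[idx], y[idx]
        G[f] = Xf.T @ Xf
        b[f] = Xf.T @ yf
        sx[f] = Xf.sum(axis=0)
        sy[f] = yf.sum()
        cnt[f] = len(idx)

    fold_fvaf = np.empty(n_folds)
    chosen = np.empty(n_folds)
    preds = []
    eye = np.eye(M)
    for test in range(n_folds):
        val = (test + 1) % n_folds
        train = [f for f in range(n_folds) if f not in (test, val)]
        nt = cnt[train].sum()
        xm = sx[train].sum(axis=0) / nt
        ym = sy[train].sum() / nt
        Gc = G[train].sum(axis=0) - nt * np.outer(xm, xm)
        bc = b[train].sum(axis=0) - nt * xm * ym
        tr_idx = np.concatenate([fold_idx[f] for f in train])
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xva, yva = X[fold_idx[val]], y[fold_idx[val]]
        best_lam, best_score = None, -np.inf
        best_model = None
        for lam in lambdas:
            w = np.linalg.solve(Gc + lam * eye, bc)
            b0 = ym - xm @ w
            lin_tr = Xtr @ w + b0
            poly, pc, psc = _fit_poly(lin_tr, ytr)
            model = WienerCascadeModel(w, float(b0), poly, float(lam), pc, psc)
            score = fvaf(model.predict(Xva), yva)
            if score > best_score + 1e-12:  # ties -> smallest lambda
                best_score, best_lam, best_model = score, lam, model
        Xte, yte = X[fold_idx[test]], y[fold_idx[test]]
        pred = best_model.predict(Xte)
        preds.append(pred)
        fold_fvaf[test] = fvaf(pred, yte)
        chosen[test] = best_lam
    return CVResult(
        fold_fvaf=fold_fvaf, chosen_lambda=chosen, fold_bounds=bounds,
        predictions=preds,
    )


def sample_trace_at_bins(trace: np.ndarray, fs_hz: float, bin_times: np.ndarray):
    """Sample a continuous behavior trace at feature-bin center times."""
    idx = np.clip(np.round(np.asarray(bin_times) * fs_hz).astype(int), 0, len(trace) - 1)
    return np.asarray(trace, dtype=float)[idx]
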