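"""Gaussian-emission sequential autoencoder for latent neural dynamics.

A compact numpy implementation of an LFADS-style variational sequential
autoencoder with autonomous dynamics and Gaussian observations.  Each trial
of z-scored spectral features ``x_t`` is compressed by a bidirectional GRU
encoder into a posterior over the generator's initial condition ``g_0``; a
GRU generator unrolls autonomously from ``g_0``; latent factors are a
time-invariant linear readout of the generator state,

    f_t = W_gf g_t,    mu_t = W_fac1 f_t,    sigma_t = exp(W_fac2 f_t) + floor,

and the observation model is ``x_t ~ N(mu_t, sigma_t^2)`` per feature.
Training maximizes the evidence lower bound (Gaussian log-likelihood minus
the KL of the initial-condition posterior from a standard-normal prior)
with Adam, full-batch, a linear KL warm-up, and gradient-norm clipping.
Gradients are computed by hand-written backpropagation through time and are
verified against finite differences in the test suite.

The exponential mapping with an additive floor keeps every sigma strictly
positive; a plain linear readout of sigma could go non-positive and break
the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialFeatureWindow",
    "GaussianLatentModel",
    "LatentTrajectories",
    "fit_gaussian_lfads",
    "denoise",
    "pcs_for_variance",
    "canonical_correlations",
    "trial_feature_windows",
]

_S_CLIP = 8.0  # pre-exponential clip for the sigma readout


# --------------------------------------------------------------------------
# GRU primitives (batch-first matrices, manual gradients)
# --------------------------------------------------------------------------

def _sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _init_gru(rng, n_in, n_hidden):
    def mat(a, b):
        s = np.sqrt(6.0 / (a + b))
        return rng.uniform(-s, s, (a, b))

    p = {}
    for gate in "zrc":
        if n_in > 0:
            p[f"Wx{gate}"] = mat(n_in, n_hidden)
        p[f"Wh{gate}"] = mat(n_hidden, n_hidden)
        p[f"b{gate}"] = np.zeros(n_hidden)
    return p


def _gru_step(p, x, h):
    """One GRU step; returns (h_new, cache).  ``x`` may be None (no input)."""

    def drive(gate, hin):
        a = hin @ p[f"Wh{gate}"] + p[f"b{gate}"]
        if x is not None:
            a = a + x @ p[f"Wx{gate}"]
        return a

    z = _sigmoid(drive("z", h))
    r = _sigmoid(drive("r", h))
    c = np.tanh((r * h) @ p["Whc"] + p["bc"] + (x @ p["Wxc"] if x is not None else 0.0))
    h_new = (1.0 - z) * h + z * c
    return h_new, (x, h, z, r, c)


def _gru_step_back(p, cache, dh_new, grads):
    """Backward through one GRU step.

    ``dh_new`` is the gradient at the step's output; returns (dx, dh_prev)
    and accumulates parameter gradients into ``grads``.
    """
    x, h, z, r, c = cache
    dz = dh_new * (c - h)
    dc = dh_new * z
    dh = dh_new * (1.0 - z)
    dc_pre = dc * (1.0 - c * c)
    grads["Whc"] += (r * h).T @ dc_pre
    grads["bc"] += dc_pre.sum(axis=0)
    drh = dc_pre @ p["Whc"].T
    dr = drh * h
    dh += drh * r
    dz_pre = dz * z * (1.0 - z)
    dr_pre = dr * r * (1.0 - r)
    grads["Whz"] += h.T @ dz_pre
    grads["bz"] += dz_pre.sum(axis=0)
    grads["Whr"] += h.T @ dr_pre
    grads["br"] += dr_pre.sum(axis=0)
    dh += dz_pre @ p["Whz"].T + dr_pre @ p["Whr"].T
    dx = None
    if x is not None:
        grads["Wxc"] += x.T @ dc_pre
        grads["Wxz"] += x.T @ dz_pre
        grads["Wxr"] += x.T @ dr_pre
        dx = dc_pre @ p["Wxc"].T + dz_pre @ p["Wxz"].T + dr_pre @ p["Wxr"].T
    return dx, dh


def _gru_run(p, xs, h0):
    """Unroll a GRU.  ``xs`` is (T, B, I) or an int T for an input-free GRU."""
    if isinstance(xs, int):
        steps = [None] * xs
    else:
        steps = list(xs)
    h = h0
    hs, caches = [], []
    for x in steps:
        h, cache = _gru_step(p, x, h)
        hs.append(h)
        caches.append(cache)
    return np.stack(hs), caches


def _gru_run_back(p, caches, dhs):
    """Backward through an unrolled GRU given per-step output gradients."""
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    T = len(caches)
    dh_carry = np.zeros_like(dhs[-1])
    dxs = []
    for t in range(T - 1, -1, -1):
        dx, dh_carry = _gru_step_back(p, caches[t], dhs[t] + dh_carry, grads)
        dxs.append(dx)
    dxs.reverse()
    return grads, dxs, dh_carry  # dh_carry is the gradient at h0


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class TrialFeatureWindow:
    """Z-scored features in a fixed peri-event window, (trials, bins, features)."""

    values: np.ndarray
    rel_times: np.ndarray  # bin times relative to the alignment event, s
    band: str = ""
    feature_ids: list = field(default_factory=list)
    trial_index: np.ndarray | None = None  # trial-table rows behind each slab


@dataclass
class GaussianLatentModel:
    params: dict
    n_factors: int
    n_features: int
    hidden_enc: int
    hidden_gen: int
    sigma_floor: float
    seed: int
    loss_history: np.ndarray = field(default=None)  # total training loss per epoch
    elbo_history: np.ndarray = field(default=None)  # deterministic full-beta ELBO


@dataclass
class LatentTrajectories:
    factors: np.ndarray  # (trials, bins, n_factors)
    mu: np.ndarray  # denoised features, (trials, bins, n_features)
    sigma: np.ndarray  # (trials, bins, n_features), strictly positive
    g0_mean: np.ndarray  # (trials, hidden_gen)


def _init_params(rng, n_features, n_factors, hidden_enc, hidden_gen):
    def mat(a, b):
        s = np.sqrt(6.0 / (a + b))
        return rng.uniform(-s, s, (a, b))

    p = {}
    for prefix, gru in (
        ("ef_", _init_gru(rng, n_features, hidden_enc)),
        ("eb_", _init_gru(rng, n_features, hidden_enc)),
        ("g_", _init_gru(rng, 0, hidden_gen)),
    ):
        for k, v in gru.items():
            p[prefix + k] = v
    p["W_mu"] = mat(2 * hidden_enc, hidden_gen)
    p["b_mu"] = np.zeros(hidden_gen)
    p["W_lv"] = mat(2 * hidden_enc, hidden_gen) * 0.1
    p["b_lv"] = np.full(hidden_gen, -1.0)  # start with modest posterior variance
    p["W_gf"] = mat(hidden_gen, n_factors)
    p["b_gf"] = np.zeros(n_factors)
    p["W_fac1"] = mat(n_factors, n_features)
    p["b_fac1"] = np.zeros(n_features)
    p["W_fac2"] = mat(n_factors, n_features) * 0.1
    p["b_fac2"] = np.zeros(n_features)
    return p


def _sub(p, prefix):
    n = len(prefix)
    return {k[n:]: v for k, v in p.items() if k.startswith(prefix)}


def _forward(p, x, eps, sigma_floor):
    """Full forward pass.  ``x`` is (B, T, R); ``eps`` the g0 noise or None."""
    B, T, R = x.shape
    xs = np.moveaxis(x, 0, 1)  # (T, B, R)
    h0 = np.zeros((B, p["ef_Whz"].shape[0]))
    hs_f, cache_f = _gru_run(_sub(p, "ef_"), xs, h0)
    hs_b, cache_b = _gru_run(_sub(p, "eb_"), xs[::-1], h0)
    e = np.concatenate([hs_f[-1], hs_b[-1]], axis=1)  # (B, 2He)
    mu0 = e @ p["W_mu"] + p["b_mu"]
    lv0 = np.clip(e @ p["W_lv"] + p["b_lv"], -10.0, 10.0)
    g0 = mu0 if eps is None else mu0 + np.exp(0.5 * lv0) * eps
    gs, cache_g = _gru_run(_sub(p, "g_"), T, g0)  # (T, B, G)
    g = np.moveaxis(gs, 0, 1)  # (B, T, G)
    fac = g @ p["W_gf"] + p["b_gf"]
    mu = fac @ p["W_fac1"] + p["b_fac1"]
    s = fac @ p["W_fac2"] + p["b_fac2"]
    s_c = np.clip(s, -_S_CLIP, _S_CLIP)
    sigma = np.exp(s_c) + sigma_floor
    recon = 0.5 * np.mean(
        np.sum(np.log(2 * np.pi * sigma**2) + ((x - mu) / sigma) ** 2, axis=(1, 2))
    )
    kl = 0.5 * np.mean(np.sum(mu0**2 + np.exp(lv0) - lv0 - 1.0, axis=1))
    cache = dict(
        x=x, xs=xs, cache_f=cache_f, cache_b=cache_b, e=e, mu0=mu0, lv0=lv0,
        eps=eps, g0=g0, cache_g=cache_g, g=g, fac=fac, mu=mu, s=s, s_c=s_c,
        sigma=sigma,
    )
    return recon, kl, cache


def _backward(p, cache, beta, sigma_floor):
    x, mu, sigma = cache["x"], cache["mu"], cache["sigma"]
    B, T, R = x.shape
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    resid = mu - x
    dmu = resid / sigma**2 / B
    dsigma = (1.0 / sigma - resid**2 / sigma**3) / B
    ds = dsigma * np.exp(cache["s_c"])
    ds[np.abs(cache["s"]) > _S_CLIP] = 0.0

    fac = cache["fac"]
    fac2 = fac.reshape(-1, fac.shape[-1])
    grads["W_fac1"] += fac2.T @ dmu.reshape(-1, R)
    grads["b_fac1"] += dmu.sum(axis=(0, 1))
    grads["W_fac2"] += fac2.T @ ds.reshape(-1, R)
    grads["b_fac2"] += ds.sum(axis=(0, 1))
    dfac = dmu @ p["W_fac1"].T + ds @ p["W_fac2"].T
    g = cache["g"]
    grads["W_gf"] += g.reshape(-1, g.shape[-1]).T @ dfac.reshape(-1, dfac.shape[-1])
    grads["b_gf"] += dfac.sum(axis=(0, 1))
    dg = dfac @ p["W_gf"].T  # (B, T, G)

    g_grads, _, dg0 = _gru_run_back(_sub(p, "g_"), cache["cache_g"], np.moveaxis(dg, 0, 1))
    for k, v in g_grads.items():
        grads["g_" + k] += v

    mu0, lv0, eps = cache["mu0"], cache["lv0"], cache["eps"]
    dmu0 = dg0 + beta * mu0 / B
    dlv0 = beta * 0.5 * (np.exp(lv0) - 1.0) / B
    if eps is not None:
        dlv0 = dlv0 + dg0 * eps * 0.5 * np.exp(0.5 * lv0)

    e = cache["e"]
    grads["W_mu"] += e.T @ dmu0
    grads["b_mu"] += dmu0.sum(axis=0)
    grads["W_lv"] += e.T @ dlv0
    grads["b_lv"] += dlv0.sum(axis=0)
    de = dmu0 @ p["W_mu"].T + dlv0 @ p["W_lv"].T
    He = p["ef_Whz"].shape[0]
    Tn = len(cache["cache_f"])
    dhs_f = np.zeros((Tn, B, He))
    dhs_f[-1] = de[:, :He]
    dhs_b = np.zeros((Tn, B, He))
    dhs_b[-1] = de[:, He:]
    f_grads, _, _ = _gru_run_back(_sub(p, "ef_"), cache["cache_f"], dhs_f)
    b_grads, _, _ = _gru_run_back(_sub(p, "eb_"), cache["cache_b"], dhs_b)
    for k, v in f_grads.items():
        grads["ef_" + k] += v
    for k, v in b_grads.items():
        grads["eb_" + k] += v
    return grads


def elbo_components(model: GaussianLatentModel, x: np.ndarray):
    """Deterministic (posterior-mean) reconstruction loss and KL."""
    recon, kl, _ = _forward(model.params, x, None, model.sigma_floor)
    return float(recon), float(kl)


def fit_gaussian_lfads(
    windows,
    n_factors: int | None = None,
    seed: int = 0,
    hidden_enc: int = 64,
    hidden_gen: int = 64,
    epochs: int = 500,
    lr: float = 5e-3,
    lr_decay: float = 0.99,
    kl_warmup_frac: float = 0.2,
    sigma_floor: float = 1e-3,
    clip_norm: float = 10.0,
    min_trials: int = 20,
) -> GaussianLatentModel:
    """Train the sequential autoencoder on (trials, bins, features) data.

    ``n_factors`` defaults to half the feature count, capped at 16.  The
    seed fully determines the fit: same data + seed -> identical model.
    Raises ``RuntimeError`` naming the seed and epoch if the loss diverges.
    """
    x = windows.values if hasattr(windows, "values") else np.asarray(windows, float)
    if x.ndim != 3:
        raise ValueError("expected (trials, bins, features)")
    B, T, R = x.shape
    if B < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {B}")
    if n_factors is None:
        n_factors = min(max(R // 2, 1), 16)
    if n_factors >= R:
        raise ValueError("n_factors must be smaller than the feature count")

    rng = np.random.default_rng(seed)
    p = _init_params(rng, R, n_factors, hidden_enc, hidden_gen)
    m_adam = {k: np.zeros_like(v) for k, v in p.items()}
    v_adam = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    warm = max(int(epochs * kl_warmup_frac), 1)
    losses = np.empty(epochs)
    elbos = np.empty(epochs)
    for epoch in range(epochs):
        beta = min(1.0, (epoch + 1) / warm)
        eps = rng.standard_normal((B, hidden_gen))
        recon, kl, cache = _forward(p, x, eps, sigma_floor)
        loss = recon + beta * kl
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged (seed={seed}, epoch={epoch})")
        losses[epoch] = loss
        grads = _backward(p, cache, beta, sigma_floor)
        gnorm = np.sqrt(sum(np.sum(g**2) for g in grads.values()))
        if gnorm > clip_norm:
            scale = clip_norm / gnorm
            grads = {k: g * scale for k, g in grads.items()}
        t_adam = epoch + 1
        lr_t = lr * lr_decay**epoch
        for k in p:
            m_adam[k] = b1 * m_adam[k] + (1 - b1) * grads[k]
            v_adam[k] = b2 * v_adam[k] + (1 - b2) * grads[k] ** 2
            mhat = m_adam[k] / (1 - b1**t_adam)
            vhat = v_adam[k] / (1 - b2**t_adam)
            p[k] = p[k] - lr_t * mhat / (np.sqrt(vhat) + adam_eps)
        r_eval, kl_eval, _ = _forward(p, x, None, sigma_floor)
        elbos[epoch] = r_eval + kl_eval
    return GaussianLatentModel(
        params=p, n_factors=n_factors, n_features=R, hidden_enc=hidden_enc,
        hidden_gen=hidden_gen, sigma_floor=sigma_floor, seed=seed,
        loss_history=losses, elbo_history=elbos,
    )


def denoise(model: GaussianLatentModel, windows) -> LatentTrajectories:
    """Posterior-mean factors, denoised features mu, and sigma per trial."""
    x = windows.values if hasattr(windows, "values") else np.asarray(windows, float)
    if x.shape[-1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {x.shape[-1]}"
        )
    _, _, cache = _forward(model.params, x, None, model.sigma_floor)
    return LatentTrajectories(
        factors=cache["fac"], mu=cache["mu"], sigma=cache["sigma"],
        g0_mean=cache["mu0"],
    )


def pcs_for_variance(data: np.ndarray, threshold: float = 0.9) -> int:
    """Smallest number of principal components reaching ``threshold``
    cumulative explained variance.  ``data`` is (samples, features)."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D (samples, features) matrix with >= 2 samples")
    xc = x - x.mean(axis=0)
    sv = np.linalg.svd(xc, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total == 0:
        raise ValueError("zero-variance data")
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def canonical_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Canonical correlations between two sample-by-variable matrices."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    qa, _ = np.linalg.qr(a - a.mean(axis=0))
    qb, _ = np.linalg.qr(b - b.mean(axis=0))
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    k = min(a.shape[1], b.shape[1])
    return np.clip(sv[:k], 0.0, 1.0)


def trial_feature_windows(
    features,
    trials,
    band: str | None = None,
    align: str = "force_onset_s",
    pre_s: float = 1.5,
    post_s: float = 0.75,
) -> TrialFeatureWindow:
    """Z-score features over the session, then window them around an event.

    Trials without a full window (or flagged invalid) are dropped.  With
    ``band`` given, only that band's columns are kept (one column per
    electrode), matching the per-band latent-dynamics fits.
    """
    vals = features.values
    sd = vals.std(axis=0)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=0)) / sd
    if band is not None:
        cols = features.columns_for_band(band)
        z = z[:, cols]
        fids = [features.feature_index[c] for c in cols]
    else:
        fids = list(features.feature_index)
    step = features.step_s
    n_pre = int(round(pre_s / step))
    n_post = int(round(post_s / step))
    rel = np.arange(-n_pre, n_post) * step
    rows, kept = [], []
    tt = trials[trials["valid"]] if "valid" in trials else trials
    for ti, ev in zip(tt.index, tt[align].to_numpy()):
        c = int(np.argmin(np.abs(features.bin_times - ev)))
        if c - n_pre < 0 or c + n_post > features.n_bins:
            continue
        rows.append(z[c - n_pre : c + n_post])
        kept.append(ti)
    if not rows:
        raise ValueError("no trials with a complete peri-event window")
    return TrialFeatureWindow(
        values=np.stack(rows), rel_times=rel, band=band or "all",
        feature_ids=fids, trial_index=np.asarray(kept),
    )
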