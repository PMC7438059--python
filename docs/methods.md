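# Methods

`gripstate` re-implements, end to end, an analysis pipeline for high-density
ECoG recorded while a subject performs a sequential movement-force finger
task: a cue, a self-paced isotonic flexion, and an isometric press to a
randomly drawn force target, with a 1-s inter-trial delay.  Because no such
human dataset is publicly deposited, every stage runs against a synthetic
session generator with known ground truth; this note documents the models,
the choices that were genuinely open, and what the synthetic results do and
do not establish.

## Synthetic sessions

Each electrode's 2-kHz signal is a sum of two band-limited carriers — a
broadband low-frequency component (8-55 Hz) and a broadband high-frequency
component (70-150 Hz) — whose instantaneous amplitudes are modulated on the
log scale:

    log a_hi,e(t) = d (w_hm g_m,e F(t) + w_hf g_f,e P(t)) + c l_e . z(t)
    log a_lo,e(t) = -d (w_lm g_m,e F(t) + w_lf g_f,e P(t)) - c l_e . z(t)

where `F` is the flexion trace, `P` the force trace, `g_m,e`/`g_f,e` two
spatially smooth gain maps whose argmax peaks are planted a configurable
distance apart, `z` a small set of smooth shared latent traces with
electrode loadings `l_e`, `d` the modulation depth (default 0.6) and `c`
the latent gain (default 0.25).  High-frequency power rises with behavior,
low-frequency power falls.  Because the modulation is log-linear, the log
band power of every electrode is — up to spectral-estimation noise — an
exact linear function of the planted envelopes and latents, which gives
every downstream stage a computable oracle (e.g. the feature matrix's
numerical rank equals `latent_dim + 2` without additive noise).

Design choices worth knowing:

* **Carriers are band-limited noise by default** (4th-order Butterworth on
  white noise, forward-backward filtered), because the Hanning/FFT band
  power of a pure sinusoid is degenerate.  A deterministic `multisine`
  carrier (harmonics of 40 Hz = 1 / the 25-ms hop, seeded random phases)
  exists for tests that need exactly repeatable window power: with it, an
  electrode with zero gain in both maps produces band features with
  essentially zero variance.
* **Movement and force are exchangeable by construction.**  Both behavioral
  traces get independent per-trial amplitudes (uniform on [0.2, 1.0]); the
  neural envelopes *are* the behavioral traces; and the band mixing weights
  are mirrored (`w_hm, w_hf = 1.0, 0.6`; `w_lm, w_lf = 0.6, 1.0`), so the
  two signals are separable from a single electrode's two bands and the two
  modes are statistically exchangeable under a band swap.  This matters for
  the spatial null: with a zero planted shift the movement and force
  decoding maps must differ only by noise, otherwise the D_inter/D_intra
  comparison has no valid type-I control.  The spatial calibration
  experiments additionally set the electrode locking probabilities to
  (0, 0, 1) — every electrode responds to both modes — so the planted peak
  shift is the only systematic map difference.  With the default mixed
  locking (0.3, 0.3, 0.4) a nonzero cross-mode map difference is a real
  property of the session, not an artifact.
* **Durations**: premovement and movement drawn from truncated normals
  (means 0.8 s and 0.4 s, SD 0.15 s, floor 0.1 s); force hold fixed at
  1.0 s; inter-trial delay 1.0 s — a ~2.5-s trial.  Force targets and
  movement excursions are uniform on [0.2, 1.0] of the maximum.
* What the generator does **not** emulate: biophysical sources, volume
  conduction, 1/f spectral background, artifacts, electrode noise
  heterogeneity, or behavioral errors other than detector-failed trials.
  Passing tests therefore demonstrate the *correctness of the analysis
  code* under the stated assumptions, not expected accuracy on real
  cortical data.

## Feature extraction

256-ms Hanning windows hopped by 25 ms (231-ms overlap), FFT power, log,
then per-channel-per-frequency-bin normalization by subtracting the
session-mean log power (i.e. the log of the geometric mean power).  The
geometric-mean convention was chosen over the arithmetic mean because it
makes a stationary channel's features exactly zero-mean; the two differ by
a per-feature constant (Euler-gamma for exponentially distributed
periodogram power), which no downstream stage can see.  A band feature is
the mean of the normalized values over the FFT bins whose centers fall
inside [lo, hi] (inclusive); at 2 kHz the resolution is 2000/512 =
3.90625 Hz.  Bin timestamps are window centers; intervals are half-open
everywhere.  A 1e-12 floor precedes the log for silent channels.  The FFT
stage runs in single precision (the features are log-scale; double
precision would change them below 1e-6) and band powers can be produced
unnormalized for the Parseval-style check against brickwall-filter
variance.

The lagged design matrix concatenates each bin with its 9 causal
predecessors (M = 2 x electrodes x 10 columns); rows with incomplete
history are dropped.

## Behavioral events

The movement signal is the first principal component of the glove sensors,
sign-oriented so flexion is positive (loading-sum rule).  Onsets are
sustained threshold crossings: movement at baseline mean + 3 SD (300-ms
pre-cue baseline, 50-ms sustain), force at 2% of the session maximum, each
then backtracked to the last sample at baseline (1 SD / zero).  The
backtrack removes the ramp-delay bias a plain threshold rule has on smooth
onsets; all thresholds are exposed in the function signature.  Modes:
premovement [cue, movement onset), movement [movement onset, force onset),
force [force onset, +0.5 s); everything else is unlabeled, and the 0.5-s
force truncation keeps the three classes roughly balanced.

## Continuous decoding

A Wiener cascade: ridge linear stage (closed form on centered sufficient
statistics) followed by a third-order polynomial fit to the linear stage's
training output.  The polynomial is stored in standardized linear-output
coordinates, which keeps prediction numerically stable when heavy
regularization collapses the linear output to a near-constant.
Cross-validation uses 11 contiguous time blocks: per test fold the ridge
strength is picked on the next block (grid 1e-4..1e4, 9 log-spaced points,
ties to the smallest), the cascade is refit on the remaining 9 blocks, and
the fractional variance accounted for, FVAF = 1 - SSE/SST (uncapped
below), is reported on the held-out block.  Contiguous blocks are used
because lagged rows share samples; shuffled folds would leak.

## Spatial maps

Per electrode, a 20-column design (2 bands x 10 lags) drives the same
cascade under 10-fold blocked CV; each fold's per-electrode test FVAF is a
map.  Peak displacement is the Euclidean distance between argmax sites in
mm (ties row-major).  The map distance D clips FVAF to [0, 1] and divides
the Euclidean distance between the fold maps by sqrt(n_electrodes), the
maximum distance between maps with unit-bounded pixels, so D is in [0, 1].
D_inter (movement fold i vs force fold j) is tested one-tailed against
D_intra with a Wilcoxon signed-rank over unordered fold pairs i < j,
pairing (D(m_i, f_j) + D(m_j, f_i))/2 with (D(m_i, m_j) + D(f_i, f_j))/2;
same-fold cross pairs have no within-mode partner and enter only the
reported D_inter set.  A Bonferroni factor is available for multi-session
batches.  Note the signed-rank pairs are not independent (all derive from
10 fold maps), so nominal p-values are approximate; the package therefore
calibrates the procedure's actual size on zero-shift synthetic sessions:
across 20-seed batches the rejection rate at alpha = 0.05 lands in the
~10-25% range, i.e. modestly anti-conservative, so nominal p-values near
the threshold should be read with that inflation in mind.

## Latent dynamics

A variational sequential autoencoder with Gaussian emissions, written in
numpy with hand-derived backpropagation through time (verified against
finite differences in the test suite).  A bidirectional GRU encoder maps
each trial of z-scored features (windowed -1.5 s to +0.75 s around force
onset, one model per band) to a Gaussian posterior over the generator's
initial condition; a GRU generator (autonomous — no controller or inferred
inputs) unrolls from a sample of it; factors are a time-invariant linear
readout of the generator state; and the observation model is
x_t ~ N(W1 f_t, diag(exp(W2 f_t) + 1e-3)^2).  The exponential-plus-floor
sigma map keeps the likelihood defined where a linear sigma readout could
go non-positive.  Training: full-batch Adam (lr 5e-3, exponential decay
0.99/epoch, gradient-norm clip 10), linear KL warm-up over the first 20% of
epochs, 500 epochs by default (200 in the pipeline), encoder/generator
hidden size 64, factors defaulting to half the feature count capped at 16.
The learning-rate decay gives near-monotone descent of the
deterministic-evaluation ELBO (>= 95% of epochs improve on a 5-epoch
smoothed basis, up to 0.1% of the total descent).  Denoising uses the
posterior mean.  `pcs_for_variance` counts the PCs reaching 90% cumulative
variance; on synthetic sessions the count on denoised features is strictly
below the raw count.

## Neural vector angle

Features are clustered by k-means (k = 3, 20 restarts, seeded) on their
z-scored trial-averaged peri-event traces; silhouettes are reported, and
the two clusters with the largest peak-to-trough modulation are kept,
tagged low/high by their members' majority band.  Per trial,
m(t) = the selected features smoothed with a centered 5-bin (125-ms)
boxcar; the reference is the mean of m over the 250 ms before the trial's
peak-force time, and theta(t) = arccos of the normalized inner product, in
degrees (norms below 1e-9 yield missing bins).  Degrees make the quantity
averageable across trials and sessions.  Mode differences use a
Kruskal-Wallis test over pooled per-bin angles with Tukey HSD on ranks
post hoc.

## Mode classification

Every labeled 25-ms bin is classified from the lagged feature matrix (the
same design as continuous decoding) by either an RBF SVM (standardized
inputs, one-vs-one) or 100 bagged decision trees, under 5-fold blocked CV;
accuracy is the fraction of correctly classified bins, median +/- IQR
across folds.  The chance level repeats the whole analysis on shuffled
labels.  Because every trial carries the same premovement-movement-force
label order, permuting whole-trial label blocks would be a no-op; the
default scheme instead rotates each trial's label block by a random
offset, preserving class priors and label contiguity while destroying
alignment.  A plain per-bin permutation is also available and is what the
balanced-class "chance = 1/3" check uses.  With unbalanced classes chance
is not 1/3, hence the empirical distribution (200 shuffles at desk scale;
1000 reproduces the original procedure).

## Problem sizes

Default study conditions: 60-trial sessions on a 4 x 4 grid at 4-mm pitch
(the spatial-map experiments use 4 x 8 so an 8-mm peak shift fits
comfortably), SNR 5-8, 24-40 trials for repeated-seed calibrations, and a
40-feature / 60-trial / 3-latent benchmark for the autoencoder.  These
sizes were chosen so each analysis has clear statistical power while a
complete run of the test suite and the acceptance script stays
desk-friendly on one CPU.

## Known limitations

* The generator's exchangeable-mode construction is deliberately idealized;
  real movement and force representations need not be equally decodable,
  and on real data the D_inter statistic would fold decodability
  differences into "spatial" differences.
* The autoencoder is the autonomous-dynamics variant; sessions whose
  single-trial dynamics require inferred inputs would need the controller
  extension.
* The Wilcoxon fold-pair test is anti-conservative under fold dependence
  (see above); its empirical size is calibrated only for the synthetic
  conditions shipped here.
* Onset detection assumes a quiescent pre-cue baseline; tremor-like
  baselines would need different thresholds (all exposed as parameters).
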