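# Methods

This note documents the models implemented in `tfflim`, the choices
made where the design was genuinely open, and what the synthetic tests
do and do not demonstrate.

## Forward model

A time-folded optical cavity replicates the fluorescence decay of each
scene pixel `n_replicas = 6` times (the direct pass plus N = 5 round
trips).  Pass *n* is delayed by `n * t_c` with `t_c = 0.59` ns,
displaced by `n * y` detector columns (default `y = 10`), and carries
the power fraction `r_n`.  A gated intensifier integrates each delayed
decay against the gate profile `G(t)`, so the clean signal at iCCD
pixel (i, j) is

    s[i,j] = sum_n r_n * Int G(t) A[i,j-ny] exp(-(t - t0 - n t_c)/tau[i,j-ny])
                         H(t - t0 - n t_c) dt .

A companion camera integrates the full decay, giving the closed form
`q = k A tau` used throughout for amplitude elimination.

**Replica weights.** Only the splitter ratio (51.5 : 48.5) is known, so
the default weight law is geometric, `r_n = 0.515 * 0.485^n` (lossless
mirrors); the full weight vector can be overridden with calibrated
values.

**Gate model.** The true gate shape of the instrument is not available;
the package uses a parametric flat top with Gaussian-smoothed edges
(`edge_sigma = 0.1` ns).  The default timing — opening 0.2 ns before
the excitation and closing 1.3 ns after it (width 1.5 ns, about 2.5
cavity periods) — was chosen by a grid search with two requirements:

1. the uncertainty-bound minimum falls near 1 ns (the regime the
   instrument is optimized for), and both target operating ranges hold
   (below);
2. the spatially-uniform-scene response `sum_n r_n I_n(tau) / tau` is
   strictly monotone in lifetime.  Late gates violate this (a 2.5 ns
   and a ~7 ns uniform scene become indistinguishable), which poisons
   CNN training labels; a gate that opens before the decay makes every
   replica term of the form `1 - exp(-c_n/tau)`, monotone by
   construction.

Under this gate the later round trips carry little gated signal (the
third replica is at the percent level for nanosecond lifetimes, later
ones are dark), consistent with late replicas being SNR-limited.
Geometry-calibration exposures therefore use a wider gate (width 4 ns)
in the tests, which makes all six replicas visible; the calibration
estimator itself is gate-agnostic.

**Quadrature.** Gate integrals use the trapezoid rule with `dt = 0.01`
ns on grids aligned to the gate support and the decay onset, so the
integrand is smooth on the grid and the error is O(dt^2) (relative
error ~1e-5 at the default step; rectangular gates integrate the bare
exponential over the exact window).  Image-scale lifetime maps with
many distinct values are evaluated through a 2048-node log-spaced
lifetime table with log-log interpolation (relative error ~1e-4);
small instances and all oracle tests use direct quadrature.

**Geometry.** Seed maps carry an upstream margin of `(n_replicas-1)*y`
columns (the 270 x 220 -> 220 x 220 recipe at the default shear);
rendered images are cropped to the FOV.  For reconstruction from
FOV-sized images, only columns `j >= (n_replicas-1)*y` have their full
replica chain in frame (the valid region); lifetimes in the centre band
additionally have all of their own replicas observed.  Non-zero shear
tilt is emulated by bilinear rotation of the rendered image.

## Detector noise

Photocathode photons P convert to photoelectrons with `DQE = 0.20`,
are amplified with gain M (default 500) and excess-noise factor F, and
accumulate readout (8 e-), dark (0.03 e-/s) and clock-induced-charge
(0 e-) noise:

    sigma^2 = sigma_read^2 + F^2 M^2 (DQE * P + sigma_dark^2 + sigma_clc^2).

Measurements are modelled as Gaussian with this SD (a strict-Poisson
signal mode exists as a cross-check; the two agree in mean and variance
for P >= 100).  Sampled images are returned in photon-equivalent units
(count-space noise divided by `M * DQE`) so a noisy image is an
unbiased estimate of the clean one.  F is never specified for the
instrument; the default F = 1.3 is a typical microchannel-plate value,
and the headline uncertainty bounds hold for F up to ~2, so the choice
is not load-bearing.

## Uncertainty lower bound

For one pixel observed through all replicas, the posterior over
lifetime is

    p(tau | s_hat) ∝ prod_n N(s_hat_n; s_n(tau), sigma_n(tau)) * p(tau),

with a uniform prior on [0.02, 20] ns discretized on 2,000 log-spaced
nodes and trapezoidal normalization.  Evaluating at the expected
(noise-free) observation gives a lower bound on the relative
uncertainty sd/tau; thermal and CMOS-side noise would only raise it.

**Photon-budget convention.** Quoted budgets behave as
photoelectron-equivalent counts: the quantum efficiency is applied
upstream of the quoted number (`budget_includes_dqe=True`, exposed as a
switch).  Under the strict incident-photon reading no gate geometry
reproduces sub-10% bounds on [0.36, 2.6] ns at 5,000 photons — the
information deficit is exactly the sqrt(DQE) factor — so the
photoelectron convention is adopted as the only one consistent with
those operating ranges.  The budget normalizes the *total* decay
(amplitude `A = B / (tau * sum_n r_n)`); the gate then selects what is
detected.

With the defaults the bound's maximum is 8.4% over [0.36, 2.6] ns at
5,000 photons and 5.1% over [0.1, 10] ns at 50,000 photons, with the
5,000-photon minimum at about 1 ns — these are the quantities
`scripts/acceptance.py` recomputes.

## Inverse retrieval

The amplitude is eliminated via `A = q/(k tau)` and the cost

    C(tau) = ||P(tau) - s_hat||_2 + alpha ||tau||_2^2

is minimized by projected gradient descent with Armijo backtracking and
a clamp at `tau_floor = 0.02` ns.  The data term is the unsquared L2
norm as specified (its gradient is the normalized residual, singular at
a perfect fit; a squared-norm flag exists).  The analytic gradient
pushes each masked residual pixel back to its `n_replicas` source
columns with the closed-form partial
`r_n q/k (I_n'(tau)/tau - I_n(tau)/tau^2)`; it matches central finite
differences to ~1e-9 relative error on small instances.  The
regularizer gradient is applied per pixel (`2 alpha tau`).

`alpha = 1e-3` was selected by a log-grid search on synthetic bead
validation data (1e-4 and 1e-3 are equivalent; larger values bias the
dim long-lifetime population).  Stopping: `max_iter = 500` default,
relative cost change below 1e-6.  Initialization is uniform random in
[0.5, 5] ns with a recorded seed; tests use the constant-init mode for
reproducibility.  Pixels with `q` below a configurable fraction of the
image maximum can be excluded from the data term (dark regions carry no
lifetime information).

Identifiability: from FOV-sized inputs the data constrain fewer columns
than there are unknowns (the upstream margin's sources are never fully
observed), so estimates near the upstream edge inherit errors that
decay over roughly two chain lengths into the image; the attached mask
marks the valid region, and the centre band is the most reliable.  For
spatially uniform scenes the per-pixel data collapse to a single
ratio, which the monotone default gate keeps invertible.

## Dilated CNN

A compact numpy CNN (explicit forward/backward passes, per-tap GEMMs,
Adam with exponential learning-rate decay): three Conv2D stages with
kernels of extent 11 along the shear axis only and dilation 10 —
taps land exactly on the +/-5 replica displacements at y = 10, a sparse
101-pixel causal receptive field — then a dense 3x3 head acting as
learned sliding-window binning.  The training loss is the
intensity-weighted MSE `mean(q * (tau_hat - tau)^2)`; internally the
weight is the normalized CMOS channel (a constant rescaling that leaves
the minimizer unchanged).  Channels are normalized by the training
set's 99th-percentile intensity, stored with the weights.

Padding: the reference configuration uses unpadded (valid) convolution
in the first dilated stage — the feature map shrinks by 100 columns,
matching the seed-margin bookkeeping — and same-padding thereafter
(`padding_policy="hybrid"`); three fully unpadded 101-span stages would
consume more columns than a 220-wide image has.  Same-convolutions pad
by *replicating* the border pixels (`pad_mode="edge"`; `"zero"`
selectable).  Zero borders look like artificial dark scenery, break
translation invariance, and in desk-scale experiments produced learned
column-position biases of ~0.3 ns on spatially uniform scenes; with
replicate padding a uniform noise-free scene is exactly translation
invariant through the whole network.  One caveat: a border pixel's
influence extends beyond the nominal receptive span through its
replicated copies, so the exact-causality guarantee applies to interior
source pixels.

Desk scale: 500 triplets of 64 x 160 pixels (image width at least the
first stage's receptive span, so padding statistics match between
training and inference), kinds cycling flat / beads / texture / flat /
beads / cell-like, feature widths (24, 12, 8) instead of the reference
(256, 64, 16), 20 epochs, batch 8, and a running average of the weights
over the final 5 epochs (`avg_epochs`) to damp the stochastic-gradient
jitter of so short a run.  With these settings the validation loss
falls roughly eighty-fold and uniform mid-range scenes are recovered
at ~0.2 ns RMSE.  The reference-scale configuration (10,000 triplets of
220 x 220, 200 epochs) is expressible but not exercised by the tests.

CNN-vs-IR agreement is assessed on noise-free bead scenes: on noisy
input at the bead photon budgets the per-pixel difference is dominated
by inverse retrieval's own stochastic scatter on the dim long-lifetime
beads (interquartile range ~1.4 ns, the counterpart of the +/-0.7 ns
population widths the physical system exhibits), not by algorithmic
disagreement.

What the synthetic benchmarks show: on scenes drawn from the same
forward model and noise budget as training, the desk-scale net recovers
uniform mid-range lifetimes to sub-0.3 ns RMS and agrees with inverse
retrieval at the sub-0.3 ns level on bead scenes.  They do not show
robustness to model mismatch (real gate shapes, optical blur,
background autofluorescence), which the synthetic generator does not
emulate.

## Shear calibration

The replica chain makes the image quasi-periodic along the shear axis.
`estimate_shear` computes the autocorrelation through the windowed 2-D
Fourier transform (Wiener–Khinchin), finds the strongest off-centre
peak within +/-10 degrees of the nominal axis, and walks outward
through the peak's harmonics (each replica pair sits at an exact
multiple of the displacement vector), refining each peak with a local
quadratic fit; the farthest harmonic fixes the tilt with the greatest
angular leverage.  A cepstral variant was evaluated and rejected (log
amplification of noise, fragile under rotation resampling).  Images
with a single visible replica raise a calibration error carrying the
autocorrelation map.  `rectify` rotates by the negated tilt with
bilinear resampling; rectification is worthwhile when scene structure
is finer than the tilt-induced replica displacement (for fat smooth
blobs the resampling loss can exceed the tilt artifact).

## Phantoms

`flat` (constant maps, level drawn from the configured ranges), `beads`
(anti-aliased non-overlapping disks; populations mirror the 2.1 ns and
4.0 ns bead dyes at radii 4 and 8 px standing in for 2 and 4 um),
`cell_like` (thresholded smoothed Gaussian random field: bright
wall-like ridges, dim interiors), and `random_texture` (independent
smooth amplitude and log-lifetime fields).  Lifetime labels default to
[0.1, 8] ns.  Bead photon loads follow the same photoelectron-
equivalent convention as the uncertainty budgets (a "50k-photon bead"
deposits 50k/DQE incident photons).  Datasets are written as 32-bit
float TIFF triplets plus a JSON manifest recording every seed; dataset
regeneration from the manifest is bit-identical, and the default
75/12.5/12.5 split reproduces the reference train/val/test proportions.

## Numerical edge cases

- Lifetimes are validated strictly positive; the IR clamp (0.02 ns)
  matches the prior's lower edge.
- Clean images are non-negative by construction; noisy images keep
  negative excursions (signed read noise).
- Degenerate posteriors (observation incompatible with the prior
  support) are flagged rather than renormalized.
- A zero-amplitude pixel contributes neither signal nor gradient; its
  lifetime is reported only through the regularizer (and masked out by
  the low-signal cut when enabled).
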