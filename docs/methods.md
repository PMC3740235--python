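# Methods

## Problem and model

`dyntexseg` segments low-contrast grayscale image time series by the
*motion pattern* of each region rather than by per-frame intensity.  The
motivating application is thrombus formation in DIC microscopy of an
injured vessel: three regions — the slowly moving thrombus, the fast
chaotic blood flow of the uncoagulated vessel, and a near-static
background — are nearly indistinguishable in any single frame but have
very different dynamics.

Every pixel carries a **dynamic-texture model**: the intensities of the
odd-sided patch centred on it, observed over a temporal window of `tau + 1`
frames, are modelled as a stable linear dynamical system

    z(t+1) = A z(t) + v(t),        y(t) - y_bar = C z(t) + w(t),

with hidden state `z` of order `n` and orthonormal observation matrix `C`.
Estimation is the classic closed-form sub-optimal solution: SVD of the
mean-subtracted data matrix gives `C` (leading left singular vectors) and
the state trajectory; `A` is the least-squares one-step predictor.  A
rank-deficient patch (near-constant intensities) is padded with the SVD's
orthonormal completion, its dead state directions zeroed, and flagged; such
"static" models still take part in distance computations.

Models are compared by the squared **Martin distance**

    d_M^2(D1, D2) = -log prod_i cos^2(theta_i),

with `theta_i` the principal angles between the column spaces of the
extended observability matrices `[C; CA; ...; CA^(n-1)]`.  Scalar distances
orthonormalize both observability matrices (QR) and take singular values of
the cross-product, clamped to [0, 1]; the vectorized path uses
`slogdet(Q1^T Q2)`, which is algebraically identical for orthonormal
factors and much faster in bulk (the two paths agree to 1e-9 in tests).
Degenerate pairs (a principal angle of 90 degrees) are infinitely far;
before entering any statistic, distances are clamped to a cap (default
1e6).

## Region statistics on the model manifold

Each region is given an approximate normal distribution through the Martin
distance: a mean model and a scalar variance.  Two mean notions are
implemented:

* **Fréchet (medoid)** — exhaustive search over the models observed in the
  region for the one minimizing the weighted sum of squared distances to a
  random sample of `|Omega_s|` region models (ties break to the lowest
  linear index);
* **Doss** — the squared distance to the mean is replaced by the weighted
  expectation of squared distances to the sample, avoiding the choice of a
  single representative.  This surrogate averages estimation noise and is
  the default.

Samples are drawn uniformly in the region and weighted by
`min(d_boundary^2, s^2)` (`s` = patch side): patches that straddle a region
boundary mix two generating processes and fit neither region, so they are
down-weighted.  The region variance is the confidence-weighted mean of the
squared distances over all region pixels, floored at 1e-6; event-map
standard deviations are floored at 1e-3.  The per-pixel negative
log-likelihood of a region is `d^2/(2 sigma^2) + log sigma`.

## Energies

* **Motion segmentation** `E_ms`: sum of the per-pixel region
  log-likelihoods over the current partition.
* **Event detection** `E_ed`: the thrombus is the only region that did not
  exist at the start of the recording, so the per-pixel Martin distance
  between the initial window's model and the current window's model (the
  *event map*) is high exactly there.  Each region scores the event map
  under a Gaussian; the vessel and background share one distribution, as
  the gradient flow assumes.
* **Tubular shape prior** `E_sp`: at each outer iteration an "infinite
  rectangle" (a band of half-width `r` about a straight centerline) is fit
  to the aortic region — centerline from the first principal axis of the
  region's pixels, radius from the median distance of boundary pixels to
  it, with Nelder–Mead refinement of (angle, offset, radius) when the
  inclination exceeds 30 degrees (PCA slope quantization degrades at steep
  angles).  Aortic pixels pay `exp(d_R^2 / 2 sigma^2) - 1` with `d_R` the
  distance transform of the band (0 inside), which prevents leakage into
  collateral branches.
* **Topological prior** `E_top`: the smoothed area of the sign class that
  is neither thrombus, vessel nor background keeps the thrombus inside the
  aorta.

## Two-level-set minimization

Thrombus = {phi1 < 0, phi2 < 0}, vessel = {phi1 > 0, phi2 < 0}, background
= {phi1 > 0, phi2 > 0}; the remaining sign class is "forbidden".  The
solver alternates (a) re-sampling the region statistics, re-fitting the
rectangle and rebuilding the per-pixel likelihood maps from the current
labels, with (b) a fixed number of explicit gradient steps

    phi <- phi - kappa * G / scale + lambda * div(g grad phi),

where `G` collects the printed data terms of the flow and `g` is either 1
(synthetic scenes) or the edge-stopping coefficient
`1 / (1 + |grad I|^2 / eta)` with `eta` the median gradient magnitude on
the current zero-level band.  Numerical choices that the equations leave
open:

* **Smoothed step functions** — arctangent family,
  `H(phi) = 1/2 + arctan(phi/eps)/pi` with `eps = 1.5` px.
* **Likelihood gauge** — the flows contain lone likelihood terms (e.g. the
  thrombus likelihood acting alone on phi2 inside the thrombus) whose sign
  semantics assume the best-fitting region has *negative* log-likelihood.
  That holds for tight textures (`sigma < 1`) but not in general, so the
  per-pixel mean over regions is subtracted from the likelihood maps before
  they enter the flow.  Pairwise-difference terms are unchanged; the MAP
  partition is unaffected; the lone terms recover their intended meaning at
  any variance scale.
* **Gradient normalization** — each field's data gradient is divided by the
  90th percentile of its magnitude on the active band (|phi| <= 3 eps) and
  clipped to [-1, 1], making `kappa` (default 0.5) a front speed in pixels
  per step.  Normalizing by the global maximum lets a single outlier pixel
  stall the rest of the interface; normalizing the two fields jointly
  starves whichever field has the smaller dynamic range.
* **Reinitialization** — the embedding functions are re-distanced (exact
  Euclidean distance transform, sign preserved) every 10 inner steps; the
  diffusion weight defaults to `lambda = 0.1` (explicit stability requires
  < 0.25).
* **Iterate averaging** — because the statistics are re-sampled every outer
  iteration the iterates jitter around the fixed point (markedly in
  Fréchet mode, where the mean is a single medoid model); the returned
  state averages the last 6 outer-iterate embedding pairs, which removes
  the jitter without biasing the converged front.
* **Convergence** — label-flip fraction below 1e-3 over one outer
  iteration, or the iteration cap.
* **Degenerate regions** — an empty region's likelihood map is set to a
  large constant so it attracts nothing; a vanished thrombus is flagged
  (not raised) so the tracker can fall back to two-region mode.

Configured defaults follow the reference configuration for real
microscopy: weights `alpha = 1, beta = 0.5, gamma = 0.1, zeta = 1.25`,
shape tolerance `sigma = 5`, order `n = 15`, window `tau = 75`, 5x5
patches, 60 model samples per region.  Synthetic scenes use
`synthetic_config()` — order 4 over a 60-transition window, 40 samples,
motion + topological terms — matching the low-order quadrature textures the
generator produces.  The vessel phantom uses `phantom_config()`
(`gamma = 30, sigma = 3`): its Gaussian *intensity* likelihood has a much
larger dynamic range than the motion likelihood, so the prior must be
weighted accordingly to express the same preference.

## Tracking

Segmentation starts at the last temporal window (where initial polygons
can be drawn around the developed thrombus) and propagates backward every
`decimation`-th frame (default 10, emulating a 25 to 2.5 fps reduction).
The vessel embedding warm-starts from the later frame's result plus the
temporal term `eps * delta(phi2) (1 - 2 H(phi2^{t+1}))` with
`eps = 1e-2`.  The thrombus embedding is instead *re-seeded* at every
active frame from the event map: the connected component of the smoothed
(sigma 3 px) event map exceeding the aortic median by one standard
deviation that overlaps the previously tracked thrombus.  Re-deriving the
thrombus from the change evidence each frame prevents the backward chain
from drifting: once the plug is small, a warm-started thrombus region
becomes a degenerate split of the vessel whose self-referential statistics
are a stable fixed point.  When no credible component remains the contour
has vanished and earlier frames run in two-region mode with an empty
thrombus — the pre-attachment regime.

The event map uses a shorter window (`tau_event = 30`) than the motion
statistics (`tau = 50` for the synthetic tracking preset): a centered
window of length `tau` smears the attachment time backward by up to
`tau/2` frames, while the motion statistics benefit from the longer
support.  Skipped frames are filled by shape-based interpolation
(thresholded linear blend of signed distance fields, applied separately to
the thrombus and aortic masks).  The thrombus surface area (TSA) is the
per-frame thrombus pixel count (physical areas use the 0.55 um x 0.56 um
pixel of the reference optics); the time to attachment (TTA) is the first
frame whose thrombus area reaches `min_area` (default 5 px — the notion of
"attachment" needs an explicit area threshold) divided by the frame rate.

## Synthetic data

The generator renders each region from quadrature sinusoid pairs: spatial
modes `cos(k.x)`, `sin(k.x)` driven by a shared damped-rotation hidden
state.  A translated patch sees a phase-rotated restriction of the same
pair, so every interior patch is an *exact* order-n LDS with a
translation-invariant observability subspace — within-region Martin
distances are small by construction, and regions are told apart by mode
orientation and state dynamics.  Three presets mirror the motion regimes
of the application: a slow coherent thrombus-like texture (spectral radius
0.96, ~1 Hz phase advance at 25 fps), a fast chaotic blood-flow texture
(radius 0.8), and a near-static background drift (radius 0.95, very slow
rotation).

Two generator properties required deliberate calibration:

* **Noise levels** (0.093–0.133 intensity std at amplitude 0.08) are chosen
  so that the three presets' estimated-model clusters have *comparable
  dispersion*, and that dispersion is comparable to the perturbation a
  patch suffers when it straddles a region boundary.  With near-noiseless
  textures every mixed boundary patch is far from all clusters and the
  ±2 px ambiguous band collapses en bloc to whichever region is loosest —
  a systematic 2 px boundary shift.  Matched broad clusters grade the
  distance profile through the band and center the recovered boundary.
  Amplitudes are kept small enough that clipping to [0, 1] affects < 0.5%
  of samples (clipping breaks the linear model).
* **Global state caveat** — each region's hidden state is shared across the
  region, so model-estimation errors are spatially *correlated* within a
  region and a window; event maps therefore compare each window against
  region-wide coherent baselines, which the tracker's candidate rule
  normalizes per-region (median + std within the aorta).

What the generator does not emulate: DIC shear-gradient optics, spatially
varying illumination, frame-to-frame registration error, cell-scale
granularity of real blood flow, or non-stationary textures within a
window.  Passing tests therefore demonstrate the machinery — estimation,
statistics, energies, minimization, tracking — under controlled conditions
matching the model's assumptions, not performance on real microscopy.

## Problem sizes

Default test/acceptance workloads: 64x64x75 three-region scenes (order-4
models, 61-frame windows, full-resolution model grid), 64x64x61 event
pairs, a 96x128 phantom, and a 96x128x300 growing-plug sequence tracked on
a stride-2 grid every 10th frame.  These sizes keep a full pipeline run in
minutes on one CPU while leaving every component in its intended regime.

## Known limitations

* Boundary localization is limited by the 5x5 patch support; under
  unmatched region dispersions the recovered boundary shifts toward the
  tighter region by up to 2 px.
* The Fréchet (medoid) mean is noticeably noisier than the Doss surrogate;
  both modes are exposed, Doss is the default everywhere.
* TTA resolution is limited by the event window (tau_event/2 frames) and
  the decimation step; on the synthetic plug scenes the absolute error
  stays within two active-frame intervals for most seeds, with occasional
  marginal seeds (weakly expressed early plug).
* The tracker assumes a single thrombus and a vessel whose boundaries move
  slowly; multiple plugs or large vessel deformation are out of scope.
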