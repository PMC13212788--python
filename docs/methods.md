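# Methods

This note documents the models implemented in `mpuscad`, the choices made
where the underlying methods literature leaves the design open, and what the
synthetic phantom does and does not establish.

## Time-intensity curve model (1D CUDI)

Linearized contrast intensity is proportional to ultrasound-contrast-agent
concentration; linearization inverts the display log compression,
`linear = 10^(dB/10)`, and is exactly invertible within the declared dynamic
range. Each voxel's TIC is fitted with the modified local density random walk
(mLDRW) model

```
C(t) = auc * sqrt(kappa / (2 pi (t-t0))) * exp(-kappa (t-t0-mu)^2 / (2 (t-t0)))
```

with `kappa` (1/s) the dispersion-related rate, `mu` (s) the mean-transit
parameter, `t0` (s) the theoretical appearance time and `auc` the curve area.
The parameterization is self-consistent: the time integral equals `auc`
exactly (Bessel `K_{1/2}` identity), the mean transit time is `mu + 1/kappa`
and the transit-time variance is `mu/kappa + 2/kappa^2`; the latter two
identities drive the moment initialization (t0 from the 5%-of-peak crossing,
`mu` from the center of mass, `kappa` from the variance identity).

Fitting is bounded nonlinear least squares (max 200 iterations, tolerance
1e-8); a fit counts as converged when the solver succeeds and R^2 >= 0.5.
Two equivalent paths exist: `fit_mldrw` (scipy Levenberg-Marquardt/TRF, one
TIC) and `fit_mldrw_volume`, a Levenberg-Marquardt vectorized across all
voxels in `(log kappa, log mu, t0, log auc)` with the analytic Jacobian.
The batched path exists purely for throughput (a 32^3 study holds ~7,000
TICs); the tests pin it to the scipy path and to the generator's truth.

Precision limits: at 5% peak-amplitude noise on a typical curve
(kappa = 2/s, mu = 20 s, 120 frames at 1 Hz) the Cramér-Rao bound already
implies ~32% relative standard deviation on `kappa`; the fitter attains that
bound (tested), so kappa maps from noisy loops are intrinsically noisy — the
classifier, not the fitter, is the place where that noise is averaged out.
The estimator's *bias* on kappa stays below 5% at that noise level.

Derived maps: kappa, mu, appearance time, peak intensity, and wash-in time
(5% -> 95% of peak on the fitted curve, evaluated on a 1024-point grid per
voxel). Missing (non-converged) voxels propagate as NaN through every feature
map and are imputed with the feature mean (0 after standardization) only at
classifier input.

## Convective dispersion (4D CUDI)

Local transport is modeled by `dC/dt = D lap(C) - v . grad(C)`. All
derivatives are central finite differences in physical units (anisotropic
spacing honored); per voxel, ordinary least squares over a 5x5x5 spatial
window and all frames estimates `(D, v)`. The window sums are computed with
box filters, so the cost is independent of window size. A voxel is
invalidated when the 4x4 normal matrix has condition number > 1e6 (constant
concentration) or when D < 0. No regularization is applied — invalidation is
preferred over biasing the estimates. Where mLDRW fits converged, the fitted
(noise-free) curves replace the raw TICs before differentiation.

The estimator was validated against the closed-form convecting-diffusing
Gaussian bolus `C(x,t) = (4 pi D (t+t_ref))^{-3/2} exp(-||x-x0-vt||^2 /
(4 D (t+t_ref)))`: on a 41^3 grid at 0.5 mm / 0.1 s sampling both D and v are
recovered within 5% (typically ~1%), errors fall monotonically under grid
refinement, and 90-degree rotations rotate `v` and leave `D` unchanged.

## TIC similarity (SA)

Per voxel, similarity with the TICs on a spatial ring (default radius 2 mm;
offsets within half a voxel of the ring radius) is averaged over neighbors:

* **corr_time** — Pearson correlation on the analysis window (from the bolus
  appearance of the mean masked TIC to 60 s later; the window carries the
  perfusion dynamics and drops the empty pre-bolus baseline);
* **coh_freq** — magnitude-squared Welch coherence (Hann window, 50% overlap,
  segment length min(32, T/2)), averaged over a band defaulting to the full
  Nyquist range. Implemented with shared segment FFTs so the whole ring reuses
  one transform; the implementation is pinned to `scipy.signal.coherence` to
  1e-12 in the tests. With L segments, independent signals bias toward ~1/L —
  a property of the estimator, not a bug;
* **mi** — plug-in mutual information with equal-frequency (quantile) binning,
  B = 16 (auto-widened with a warning when the window has fewer than B^2
  samples). Quantile binning makes the marginals uniform, the estimate
  invariant under monotone amplitude transforms, and MI(X,X) = log2(B)
  exactly when the sample count divides B.

## Velocity entropy (VE)

Arrival time tau = earliest time the fitted TIC reaches 50% of its peak
(dense evaluation; linear inter-frame interpolation on raw TICs). A local
plane fit of tau over a window (default 5^3 at phantom scale, 7^3 in the
module default) gives the slowness `grad tau`; flow points opposite the
gradient with speed `1/||grad tau||`. Voxels with `||grad tau||` below
1e-3 s/mm are invalid: a flat tau means the front crossed faster than the
frame rate resolves.

Directions are quantized into 8 azimuth x 3 elevation bins. Two deliberate
robustness choices: azimuth bins are offset by half a bin with wraparound, and
the elevation-bin count is odd, so that *every* axis-aligned direction —
including flow along the +-pi azimuth seam and in the transverse plane — falls
mid-bin rather than on an edge where numerical noise would split it.
Components below 1e-9 are snapped to zero for the same reason.

H and H_cond are estimated from one pooled joint histogram of face-adjacent
direction pairs (3 axis pairings) inside the window: H is the entropy of the
center marginal and H_cond = H(joint) - H(neighbor marginal). Using a single
histogram for both makes `0 <= H_cond <= H <= log2(n_bins)` hold exactly,
which a two-histogram estimate would only satisfy approximately. The price is
that H is a pair-weighted direction histogram rather than a plain voxel
histogram; for interior windows the two coincide up to boundary effects.

## Shear-wave elastography

* **Loupas autocorrelator**: `v = c_us PRF/(4 pi f_c) * arg(sum_gate
  x[m, n+1] conj(x[m, n]))`, lag-one along slow time with axial-gate
  averaging; phases within 5% of +-pi are flagged as aliased.
* **Time of flight**: for each depth and adjacent lateral pair, the delay is
  the argmax of the normalized cross-correlation with parabolic sub-sample
  refinement (exact for the Gaussian pulse shapes the phantom emits, and the
  standard choice for real pulses); `sws = spacing/delay`. Non-positive delays
  (reverse propagation — the tracker assumes one-directional outward travel)
  and correlation peaks below the 0.6 quality floor are missing.
  `E = 3 rho c^2` with rho = 1000 kg/m^3 (soft tissue) holds exactly by
  construction.
* **Stacking**: the 25 planes form a fan about the probe axis; a voxel's value
  is linearly interpolated between the two nearest plane angles at its
  (radius, axial) in-plane coordinates. Voxels outside the fan or footprint
  are missing.

## Reference standard

The in-plane autocorrelation of the centered binary label field is measured on
the histology slices (FFT autocorrelation, radially averaged, pooled over
slices with overlap-count normalization) and fitted with `exp(-r/L)`; the
exponential family is the simplest monotone isotropic model and its length is
validated against a brute-force pairwise estimate. Single-class slice stacks
degrade to a prior-only model; an all-benign stack gets a 0.01 prior floor
with a warning.

Interpolation is simple kriging `p(x) = m + k' K^{-1} (y - m)` with the
prevalence prior as mean. The data for an off-slice voxel are the two nearest
slices' labels within an in-plane support radius of 3 correlation lengths
(covariance decay makes the truncation error negligible, and a global solve
over ~10^7 voxels would be infeasible). Because the covariance is stationary
and the stencil is shared, the weights are solved once per z-level and applied
as array shifts — mathematically identical to per-voxel kriging, orders of
magnitude faster. On-slice voxels copy their labels exactly; beyond-edge
stencil points contribute the prior (zero anomaly). Labels are `p >= 0.5`;
soft-target training (using p itself) is available via the reference's `p`
but hard labels plus confidence weights are the default. The weight
`w = alpha/(p(1-p) + alpha)`, alpha = 0.2, is bounded in (alpha/(0.25+alpha),
1] = (0.444, 1].

## Classifier

Default architecture (47,269 trainable parameters): per branch, three valid
3x3x3 convolutions (widths 12, 12, then a 16-wide embedding) over a 7^3
patch; the branch count of conv layers follows from the patch size so that
the output is 1x1x1. The MLP takes the three 16-vectors plus standardized
prostate volume and PSA density through hidden widths 112 and 48 to a sigmoid.
Four location channels (prostate mask, PZ mask, distance to probe / 100 mm,
fan elevation angle / pi) are appended to every branch input. All weights are
float32; He initialization; training is Adam (lr 1e-3) without weight decay.

Protocol, in order: per-feature z-scoring (dataset-wide statistics by default,
matching the protocol the classifier reproduces; a leakage-safe
train-folds-only mode is provided and recommended for new experiments);
stratified 7-fold patient-level CV with subgroups = no-csPCa plus lesion-size
terciles, round-robin within subgroup after a seeded shuffle; branch
pretraining on 50%-positive balanced batches (epoch = one pass over the
minority class); MLP fine-tuning at 5% prevalence with branch weights frozen
(bitwise-checked); confidence-weighted BCE on logits (clipping at 1e-7 in the
probability-space form); AWGN (sigma 0.1 on standardized inputs) plus a
per-sample per-feature constant offset (±0.1) as augmentation — "offset" is
read as an intensity offset, with spatial shifts deliberately out of scope;
early stopping when the best validation AUC is outside the last 10 epochs or
the loss range over 10 epochs is < 1e-4, best-AUC weights restored; max 100
epochs. Greedy forward selection adds the candidate feature maximizing mean
validation AUC until the gain is <= 0.001. The control classifier is the same
scaffold with a single branch fed only the location channels and no clinical
scalars.

Everything is deterministic given the seed: a run's global seed fans out to
per-patient, per-fold and per-repeat seeds through SHA-256 of the index tuple.

## The phantom, and what passing tests show

The phantom emulates the *structure* of the clinical inputs: an ellipsoidal
prostate (TZ core, PZ shell) with ellipsoidal lesions placed and scaled to a
5% malignant-voxel prevalence (re-drawn when grid quantization makes the
target band unreachable, failing explicitly otherwise); mLDRW TICs with
spatially smooth class-dependent parameters (benign and malignant ranges
overlap but differ; 1 Hz frames, 120 s loop); optional uniform arrival-time
gradients and in-lesion arrival jitter to create ordered vs. disordered flow;
propagating Gaussian shear pulses with class-dependent speed on 25 fan planes
(4 kHz tracking PRF); binary histology slices every 4 mm; PSA correlated with
lesion burden. ~30% of synthetic patients have no lesions, mirroring the
clinical cohort mix.

It does **not** model speckle, attenuation, probe motion, acoustic wave
physics, nonlinear bubble response, or registration error. Consequently the
end-to-end experiment demonstrates that the pipeline is *correct and
self-consistent* (estimators recover generator truth; the trained classifier
separates classes whose features genuinely differ; the control model captures
only positional signal), not that any particular clinical accuracy would be
attained on patients.

## Problem sizes

The default end-to-end experiment uses 40 patients on 32^3 grids (2 mm
voxels, ~44 cc prostates — matching the clinical median volume), 7-fold CV
with 2 repeats, 300 training voxels sampled per patient (positives capped at
one quarter), a reduced classifier (5^3 patches, widths 6/6, embedding 8,
MLP 32/16) and 8-epoch training with patience 3. These sizes keep a complete
run on one CPU core in the ten-minute range while leaving the phantom classes
clearly separable; the full 47k architecture and 100-epoch protocol remain the
module defaults and are exercised by the architecture and training-contract
tests. All sizes are configuration, not code.

## Known limitations

* The dispersion estimator fits the PDE locally; the closed-form
  spatio-temporal solution is an extension point, not implemented.
* The time-of-flight tracker assumes outward one-directional propagation;
  reflected or reverse waves yield missing voxels rather than estimates.
* Plug-in MI and coherence carry the usual positive small-sample biases; the
  tests bound them rather than correct them.
* The kriging variance (and hence a spatially varying confidence beyond
  p(1-p)) is not propagated.
* Forward feature selection retrains from scratch per candidate; at the
  default architecture this is expensive and is therefore exercised at reduced
  scale in the tests.
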