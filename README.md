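# mpuscad

Voxel-wise detection of clinically significant prostate cancer (csPCa) from
quantitative 3D multiparametric ultrasound (mpUS), with a synthetic-phantom
test bench that exercises the entire pipeline end to end.

The package is aimed at researchers in quantitative ultrasound and
computer-aided diagnosis who want a fully reproducible, CPU-only reference
implementation of the following chain:

1. **Contrast-enhanced ultrasound (CEUS) features.** Log-compressed intensities
   are linearized back to contrast-agent concentration and each voxel's
   time-intensity curve (TIC) is fitted with the modified local density random
   walk (mLDRW) indicator-dilution model

   `C(t) = auc * sqrt(kappa / (2 pi (t - t0))) * exp(-kappa (t - t0 - mu)^2 / (2 (t - t0)))`

   giving the 1D CUDI (contrast ultrasound dispersion imaging) features
   (kappa, mu, appearance time, peak intensity, wash-in time). Spatiotemporal
   4D CUDI features follow: local blood velocity `v` and diffusion `D` by
   least-squares regression of the convection-diffusion equation
   `dC/dt = D lap(C) - v . grad(C)` over neighboring TICs; similarity of
   neighboring TICs (Pearson correlation, Welch spectral coherence, mutual
   information); and the Shannon/conditional entropy of the blood-velocity
   direction field estimated from contrast arrival-time delays.
2. **Shear-wave elastography (SWE).** Particle velocity via the 1D Loupas
   autocorrelator, `v = c_us PRF / (4 pi f_c) * arg(sum x[n+1] conj(x[n]))`;
   shear-wave speed by time-of-flight cross-correlation between adjacent
   lateral positions; Young's modulus `E = 3 rho c^2`; 25 fan planes stacked
   and linearly interpolated onto the 3D grid.
3. **Probabilistic reference standard.** Histology provides binary labels only
   on 4 mm transverse slices; Wiener (simple-kriging) interpolation with an
   exponential autocorrelation fitted on the slices yields a dense csPCa
   probability `p` that honors the slices exactly and relaxes to the ~5%
   dataset prevalence far from them. Each voxel carries a confidence weight
   `w = alpha / (p(1-p) + alpha)` with `alpha = 0.2`.
4. **Classifier.** A ~47k-parameter three-branch 3D CNN + MLP (branches for
   CUDI 1D, CUDI 4D and SWE; location channels into every branch; prostate
   volume and PSA density at the MLP), trained with stratified 7-fold CV,
   50%-balanced branch pretraining, 5%-prevalence MLP fine-tuning with frozen
   branches, confidence-weighted cross-entropy, Adam, AWGN + offset
   augmentation, early stopping, and greedy forward feature selection. A
   location-only control classifier quantifies positional shortcut learning.
   The network runs on plain numpy — no GPU framework required.
5. **Evaluation.** Confidence-weighted ROC AUC (weighted Mann-Whitney),
   Youden's J operating point, per-zone (peripheral/transitional) results, and
   repeated-CV aggregation.

No clinical data ship with the package: the `phantom` module generates
synthetic patients (anatomy, CEUS loops, SWE movies, histology slices,
clinical scalars) with known ground truth, which makes every estimator
testable against its generator.

## Worked example

```python
import numpy as np
from mpuscad import (PhantomConfig, generate_study, fit_mldrw_volume,
                     confidence_weights)

study = generate_study(PhantomConfig(grid_shape=(24, 24, 24),
                                     voxel_size_mm=2.5, seed=11, n_swe_planes=6))
print(f"prevalence: {study.prevalence:.4f}")
fits = fit_mldrw_volume(study.ceus_loop)
m = study.prostate_mask
err = np.abs(fits["kappa"] - study.truth_maps["true_kappa"])[m]
print(f"median |kappa error|: {np.nanmedian(err):.2e} 1/s")
print(f"weight at p=0.5: {confidence_weights(np.array([0.5]))[0]:.4f}")
```

prints

```
prevalence: 0.0490
median |kappa error|: 6.70e-08 1/s
weight at p=0.5: 0.4444
```

— the noiseless phantom TICs are recovered to solver precision, and the
confidence weight at maximal label uncertainty equals 0.2/0.45.

The same pipeline is scriptable from the shell:

```bash
mpuscad phantom  --out run/phantom --seed 1
mpuscad features --data run/phantom --out run/features --seed 1
mpuscad reference --data run/phantom --out run/reference
mpuscad run-all  --out run/full --seed 1      # cohort, training, evaluation
mpuscad evaluate --results run/full
```

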