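# tlct — sensitivity-artifact correction for Talbot–Lau phase-contrast CT

In a Talbot–Lau grating interferometer the measured phase signal of a voxel
is scaled by a *position-dependent sensitivity*

```
S(r) = 2π (d/p₂) · (1 + r/l)      object between G0 and G1
S(r) = 2π (d/p₂) · (1 − r/d)      object between G1 and G2
```

where `r` is the voxel's distance from the phase grating G1, `l` and `d` are
the grating distances and `p₂` the analyzer period.  When a thick object
rotates in such a setup, each voxel is weighted differently at every
projection angle, so the acquisition is a **weighted Radon transform**

```
p(θ, t) = ∫ S(r) · x(r) dr        (integral along the ray of angle θ)
```

Standard filtered back-projection (FBP) of such data shows a characteristic
ramp artifact across the object.  This package — aimed at phase-contrast CT
researchers who want to compare correction strategies on controlled synthetic
data — implements the acquisition model and four reconstruction/correction
approaches:

* **FBP** (Ram–Lak filter): the uncorrected baseline.
* **Mean correction**: FBP divided by the iso-center sensitivity
  `(s_min + s_max)/2`; exact for a 2π scan, leaves the ramp artifact for a π
  scan.
* **Weighted iterative reconstruction**: algebraic least squares
  `min ½‖BWx − p‖²` solved by relaxed per-angle Kaczmarz/SART updates
  `x' = x + step·(pᵢ − bᵢWx)/(bᵢWWᵀbᵢᵀ)·Wᵀbᵢᵀ` with total-variation (TV)
  regularization, adaptive step size (start 0.75) and Lagrangian multiplier
  (start 0.5), 500 sweeps.
* **Learned correctors** (numpy, manual backpropagation): a
  **known-operator network** — trainable Ram–Lak-initialized detector filter,
  fixed back-projection, trainable per-pixel normalization and voxel-weight
  fields, whose untrained output *exactly* equals the mean-corrected FBP —
  and a standard depth-4, 16-channel **U-net** operating on uncorrected FBP
  images, both trained with MAE loss and Adam on random binary-blob phantoms.

All experiments are fully synthetic (Shepp–Logan and blob phantoms, Poisson
photon-counting noise); an adapter (`run_slice_experiment`) accepts any
normalized 2-D grayscale slice.

## Worked example

```bash
cat > cfg.yaml <<'YAML'
geometry: {n_angles: 128, n_detector: 128, image_shape: [128, 128],
           angle_offset: 1.5707963267948966}
profile:  {s_min: 0.1, s_max: 0.9, extent: 128}
iterative: {n_iterations: 150}
YAML
tlct run general --config cfg.yaml --out out/
```

prints (128×128 scale):

```
fbp        MAE 0.0774  SSIM 0.6330  PSNR 20.55 dB  MAPE 50.51%
mean       MAE 0.0255  SSIM 0.9674  PSNR 30.10 dB  MAPE 9.40%
iterative  MAE 0.0129  SSIM 0.9871  PSNR 34.55 dB  MAPE 5.83%
```

Reading the numbers: the uncorrected FBP of the sensitivity-weighted
sinogram recovers roughly half the true gray values (the iso-center
sensitivity is 0.5), hence the large MAE and the ≈0.64 SSIM typical of a
uniform 2× intensity error.  The mean correction fixes the global scale but
keeps the left-low/right-high ramp across the object; the TV-regularized
iterative reconstruction removes most of the remaining artifact.  `out/`
also receives the metric table (`metrics.csv`), reconstruction/difference
images windowed to ±0.25, and a central line plot.

The same pipeline runs from Python:

```python
import numpy as np
from tlct import (GeometryConfig, SensitivityProfile, shepp_logan,
                  weighted_forward_project, fbp, mean_correct)

geom = GeometryConfig(angle_offset=np.pi / 2)      # 400x400, 400 angles over pi
prof = SensitivityProfile()                        # linear ramp 0.1..0.9
sino = weighted_forward_project(shepp_logan(400), geom, prof)
recon = mean_correct(fbp(sino), prof)
```

Training data and the learned correctors are produced with
`tlct make-data` / `tlct train`, or `make_training_set`, `train_known_op`
and `train_unet` from Python.

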