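# Methods

## Acquisition model

The object is a square pixel grid (default 400×400, 1 mm spacing) rotating
in a fixed parallel-beam Talbot–Lau interferometer.  The interferometer
sensitivity is modeled in two forms:

* the physical form `S(r) = 2π(d/p₂)(1 ± r/·)` with the grating distances,
  used only for parameter studies (`physical_sensitivity`);
* the normalized form used by every experiment: a linear ramp from
  `s_min = 0.1` to `s_max = 0.9` over `extent = 400` voxels, centered on the
  rotation axis, clamped to its endpoint values outside.  The ramp attains
  both endpoints exactly (`ramp(i) = s_min + (s_max−s_min)·i/(extent−1)`).

The ramp is fixed in the laboratory frame along the beam direction while the
object rotates, so a voxel is weighted more strongly at angles where it sits
closer to the phase grating.  Angles are measured counter-clockwise from the
detector axis; the first projection of the experiment drivers is at `π/2`,
which orients the residual ramp artifact of a π scan along the horizontal
image axis (the orientation the package's line plots use).  For a
voxel at polar position (ρ, φ) the mean weight over a π scan deviates from
the iso-center value by `(2/π)·slope·ρ·sin(φ − θ₀)`, which is the source of
the artifact and of its dependence on the trajectory start θ₀.

### Projector discretization

Forward projection, back-projection and the row normalizations of the
algebraic update are all derived from one discretization: rays sampled at
unit steps (in pixel units) along the beam, bilinear interpolation on the
grid, each sample multiplied by the ramp value of its position along the
beam axis.  Because the weight depends only on the coordinate along the
beam, the per-step weight vector is shared by all angles and detector bins.
The adjoint is the exact transpose (inner-product identity holds to ~1e−16),
and `row_norm` returns the exact squared row norms of the discretized system
matrix — overlapping bilinear footprints of consecutive samples included —
computed by scatter-accumulating each ray's matrix row.  Rays that miss the
grid contribute exact zeros and their normalization is floored at 1e−12.
Kernels are JIT-compiled with numba.

### FBP normalization

Detector rows are convolved with the standard band-limited spatial Ram–Lak
kernel (`h[0] = 1/4dt²`, odd taps `−1/(πm dt)²`) in the frequency domain.
The back-projection is scaled by `min(angular_range, π)/n_angles`, so a 2π
scan — where every line is measured twice — is normalized consistently with
a π scan; this makes the analytic full-scan property hold: FBP of a 2π
weighted acquisition divided by the iso-center sensitivity 0.5 recovers the
phantom (in-ROI MAE < 0.02, limited only by discretization).

### Poisson noise

The noise mapping from line integrals to photon counts is a Beer–Lambert
transduction: integrals are scaled so their maximum corresponds to an
attenuation of `μ_ref = 4` (transmission e⁻⁴ ≈ 0.018, a realistic dynamic
range), counts are drawn as `Poisson(N₀·exp(−p_norm))` with blank count
`N₀ ∈ [10⁴, 10⁵]`, zero counts are clamped to one, and the log transform
maps back.  The per-bin standard deviation follows the delta-method
prediction `1/√(N₀·exp(−p_norm))` (verified by Monte Carlo).  The mapping
itself is a package choice; noise-level curves are therefore validated as
monotonicity properties, not value-matched.

## Weighted iterative reconstruction

`min ½‖BWx − p‖²` is solved SART-style: per iteration all angles are visited
once in a seeded shuffled order, each applying the relaxed normalized row
update for all bins of that angle simultaneously.  The volume is initialized
with the uncorrected FBP; 500 iterations; step size starts at 0.75.

The weighted inverse problem is ill-conditioned — without regularization the
data-consistent solution stalls visibly away from the phantom — so the TV
regularizer is what selects the smooth solution.  After each sweep,
`tv_inner_steps = 10` normalized TV sub-gradient steps are applied, each
changing a pixel by at most `λ·tv_scale` with the Lagrangian multiplier λ
starting at 0.5.  Keeping the TV step proportional to λ (rather than to the
decaying update magnitude) lets the iteration settle into a data/TV
equilibrium whose smoothing level is set by λ; `tv_scale = 3e−2` was
calibrated once so that this equilibrium at the reference 400×400/400-angle
protocol reproduces the reference smoothing level (in-ROI MAE ≈ 0.008), and
is held fixed everywhere.  The equilibrium error scales roughly linearly
with `tv_scale` and with resolution, so small-grid unit tests pass a
proportionally smaller value (4e−3 at 48–64 px).

Adaptation rules (the underlying study leaves them open): the data residual
is streamed during each sweep; if it exceeds the previous sweep's value by
more than 10 % (shuffled orders make it wobble a few percent), the sweep is
reverted, the step halves and λ decays by 0.5 %.  If the step underflows
1e−4 the image can no longer change and the iteration stops early, returning
the residual trace at its actual length.  A divergence guard aborts if the
residual grows past 10× its initial value.  No positivity constraint is
applied.

## Learned correctors

Implemented in numpy with manual backpropagation (`tlct.nn`: im2col
convolutions, 2×2 max-pool, 2×2 transposed convolutions, Adam); all
gradients are finite-difference checked.

**Known-operator network.**  `y = BP(h ⊛ p) ⊙ n ⊘ v` — a trainable
detector-axis filter `h` (spatial, length `2·n_detector−1`, applied as a
'same'-size linear convolution via FFT, initialized with the Ram–Lak
kernel), the fixed unweighted back-projection with the FBP normalization, a
per-pixel normalization field `n` (init 1) and a per-pixel voxel-weight
field `v` (init iso-center sensitivity 0.5).  The linear (zero-padded)
convolution makes the initialization identity exact: the untrained network
output equals the mean-corrected FBP to machine precision.  The gradient of
the filtered sinogram is routed through the forward projector (the exact
adjoint of the embedded back-projection).  Only the `n`/`v`
ratio is identified when the filter is free; the parameter-recovery
experiment (constant sensitivity `c`: `v/n → c`) therefore freezes the
filter via `train_params=("norm", "voxel")`.

**U-net.**  Depth 4, 16 initial feature channels, two 3×3 convolutions +
ReLU per block, 2×2 max-pool down / transposed-convolution up, skip
concatenations, zero-initialized final 1×1 convolution.  Input is the
uncorrected FBP reconstruction; the network predicts the corrected image
directly (a `residual` switch exists but is off by default).  Inputs not
divisible by 2⁴ are zero-padded and cropped back (400 → 416).  Batch size 4,
zero padding, MAE loss, Adam, early stopping with patience 20 on validation
MAE with best-weights restore.

**Training data.**  Random blob phantoms: 1–6 ellipses (uniform count), radii
uniform in 2.5–20 % of the image width, rotation uniform, one constant gray
value per blob drawn uniformly from (0, 1]; overlaps combine by maximum so
every component stays binary.  Per-item seeds are a counter off the master
seed, making datasets bit-reproducible.  The full protocol is 1000 phantoms
with an 800/200 train/validation split and 100 epochs at learning rate 1e−4;
training both networks at the full 400×400 protocol takes far longer than
the desk-scale experiments, so the test suite and the acceptance script run
a scaled-down training (64×64 geometry, 32 phantoms, 24/8 split, 5 epochs)
and check that both correctors push validation MAE strictly below the
mean-corrected baseline.  Two smoke-scale rates differ from the
full protocol for stability at few steps: the known-operator network trains
at 3e−5 (Adam's per-parameter normalization otherwise distorts the tiny
off-center Ram–Lak coefficients within a few dozen steps) and the U-net at
1e−3 (1e−4 barely moves a freshly initialized network in 30 steps).

## Evaluation

Metrics are computed in a centered circular region of interest of radius
0.25× the image width, covering the phantom interior.  MAE, PSNR and MAPE
use their standard definitions (PSNR capped at 200 dB for identical images;
MAPE excludes reference pixels below 0.01 to avoid division blow-up; data
range = reference maximum).  SSIM is evaluated with a single window spanning
the ROI (global luminance/contrast/structure moments, constants
C₁=(0.01·L)², C₂=(0.03·L)²); under this convention a uniform c-fold
intensity error scores `(2c/(1+c²))²` — ≈ 0.64 for the half-amplitude
uncorrected FBP — while a sliding-window SSIM collapses toward zero in
zero-valued regions (ventricles, air) and cannot reach the reference scores
of globally rescaled reconstructions.  A 7×7 Gaussian-weighted windowed mode
remains available (`ssim(..., windowed=True)`).

The noise sweep uses photon counts {10 000, 25 000, 50 000, 75 000,
100 000} (the stated range, 5-point grid) and reports PSNR/MAPE against the
noise-free ground truth, alongside a reference `gt_fbp` channel (FBP of the
noisy *unweighted* sinogram).  Its defining properties — reference PSNR
strictly increasing, reference MAPE strictly decreasing, iterative PSNR
within a 2 dB band — are evaluated at 128×128 with 150 iterations; the
iterative equilibrium is resolution-calibrated for 400×400, so at 128 the
TV is comparatively stronger, which only reinforces the
noise-insensitivity being tested.

## What the synthetic data do and do not show

The generators emulate the geometry of the reference experiments:
piecewise-constant objects, an exactly linear sensitivity, an ideal
photon-counting detector, and a matched projector for simulation and
reconstruction (no detector blur, no phase wrapping, no grating truncation,
no differential-phase measurement — line-integral data are used directly).
Passing tests therefore demonstrate correctness of the operators and the
relative behavior of the correction methods under the stated model, not
performance on measured interferometer data.  The TV-regularized method is
flattered by piecewise-constant phantoms; the learned correctors are trained
and tested on the same synthetic distribution.

## Known limitations

* Parallel-beam, 2-D only; the fan-beam sensitivity appears only as the
  closed-form `physical_sensitivity`, not as a projector.
* The iterative adaptation rules and `tv_scale` are package choices
  calibrated at the reference protocol; at other resolutions the equilibrium
  smoothing differs proportionally.
* Full-protocol network training (1000 phantoms × 100 epochs at 400×400) is
  supported but takes hours on one CPU; shipped experiments use the
  scaled-down protocol above.
* The known-operator filter/weight decomposition is only identified up to a
  joint rescaling unless part of the parameters is frozen.
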