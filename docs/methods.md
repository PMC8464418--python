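# Methods

## Acquisition model and Fourier convention

The package models single-slice Cartesian MR acquisition as
`y = m ⊙ (G x + ε)`: the complex image `x` (n_x × n_y) is mapped to
k-space by `G`, masked by a binary template `m`, and corrupted by complex
Gaussian noise drawn i.i.d. at the *sampled* indices only, with standard
deviation `noise_sigma` per real/imaginary component (complex variance
2σ²).  Unsampled entries of `y` are exactly zero by construction.

`G` is the centered, unitary 2D DFT: `fftshift ∘ fft2(norm="ortho") ∘
ifftshift`.  Unitarity makes Parseval's identity exact, the adjoint equal
to the inverse, and the data-consistency blend independent of any scaling
convention.  Both properties are asserted in tests at 1e-12/1e-10 and
against an independently constructed dense DFT matrix on 8×8 grids.

Masks undersample whole phase-encode columns (rows = frequency encode,
always fully sampled): `round(n_pe / R)` columns are kept, of which
`round(center_fraction · n_pe)` form a contiguous fully sampled central
band and the rest are drawn uniformly without replacement.  The default
`center_fraction = 0.08` is the conventional choice for CNN-reconstruction
training data; a fully sampled low-frequency core stabilizes training and
matches clinical practice.  The sampled fraction is within one line of
1/R; an `R` so large that no lines remain beyond the central band is
rejected.

## Synthetic data

No clinical images ship with the package; all experiments run on seeded
synthetic objects.

* **Random-ellipse phantoms** (default training/evaluation object):
  `n_ellipses` ellipses with uniform random centers (±0.65 of the
  half-field), semi-axes (0.08–0.45), orientation and signed intensity
  (−0.5 to 1.0), summed and clipped to [0, 1].  Piecewise-constant images
  with sharp edges are the standard analytically checkable MR test
  object, and the random family gives an unlimited i.i.d. corpus.
* **Shepp-Logan mode**: the canonical ellipse table with the modified
  (Toft) contrast values, so intensities stay in [0, 1]; verified in tests
  against a brute-force per-pixel rasterization of the published table.
* **Phase**: phantoms are real by default; an optional smooth low-order
  polynomial phase map (flag `smooth_phase`) exercises the complex code
  paths the way real acquisitions do, leaving magnitudes unchanged.
* **Coil sensitivities**: each coil is a random low-order Fourier
  expansion (≤ 2 cycles across the field of view, coefficients decaying
  with frequency, plus a dominant uniform term), normalized so the root
  sum-of-squares is exactly 1 per pixel.  Synthesizing in a bandlimited
  basis makes the smoothness contract (< 1% of spectral energy above a
  quarter of the Nyquist radius) hold by construction rather than by
  tuning; SOS normalization then makes the root-sum-of-squares of the
  fully sampled coil images equal the object magnitude, which is the
  network's label in multi-coil mode.
* **Datasets**: a master seed spawns one `SeedSequence` substream per
  sample (phantom, mask, noise), so sample *i* is independent of how many
  samples precede it and every pair is reproducible from its recorded
  mask and k-space.  At R = 1 with σ = 0 the dataset is an identity
  dataset up to FFT round-off (~1e-16).

What the generator does **not** emulate: anatomy, coil coupling, motion,
off-resonance, non-Cartesian trajectories, and the intensity statistics of
real tissue (real MR backgrounds contain noise, phantom backgrounds are
exactly zero — see Limitations).  Passing tests therefore demonstrate the
correctness of the operators and the qualitative behavior of the methods,
not clinical performance.

## Data-consistency layer

For a candidate reconstruction `x_cnn` and measurements `y`, the layer
solves `min_x ‖x − x_cnn‖² + λ‖G_u x − y‖²`.  Because `G` is unitary and
the mask diagonal, the normal operator `I + λ G_uᴴ G_u` is diagonal in the
frequency domain and the solution per index is

    Y_i = (T_cnn,i + λ T_0,i) / (1 + λ)  on the sampled set C,
    Y_i = T_cnn,i                        elsewhere,

a convex combination of prediction and measurement.  λ weighs measurement
trust and should grow as the noise level falls; `λ = inf` is exposed as an
explicit hard-replacement mode because the package's default experiments
are noiseless, where exact consistency is optimal.  The implementation is
verified against a dense least-squares solver (`dc_least_squares_oracle`,
explicit n × n system) on random 4×4/8×8 instances to 1e-10, and obeys
monotonicity in λ and idempotence at λ = inf as property tests.  The layer
is linear in both inputs and self-adjoint up to its real diagonal, so its
backward pass is the same frequency-domain blend with the data term
dropped.

## Network and training

Default architecture: 3 convolutional layers (3×3 kernels, 32 hidden
channels, ReLU between layers, linear output), residual — the network
predicts a correction added to the zero-filled input, the standard
formulation for de-aliasing.  Complex images travel as two real channels;
multi-coil blocks as 2·n_coils channels with per-coil DC and an SOS
combination head.  In residual mode the output layer initializes to zero,
so a fresh network is exactly the identity map: training starts from the
zero-filled baseline, and a network built for an already-solved task
(full sampling) starts at zero loss.  Remaining layers use seeded He
initialization.

The loss is the mean (per-pixel) squared error of the complex difference.
The mean rather than sum convention makes learning rates transferable
across image sizes; the two differ only by the constant pixel count.

Training is minibatch Adam (default lr 1e-3, batch 8) or plain SGD, fully
deterministic given the two seeds (initialization, shuffling).  The whole
stack is NumPy with hand-derived gradients — convolution backward as
correlation with the flipped transposed kernel, DC backward as the blend's
diagonal, SOS backward as the per-pixel quotient rule — validated against
central finite differences to better than 1e-6 relative in float64.
Training runs in float32 by default, the usual precision for conv nets; a
float64 mode exists for precision-sensitive checks.  One caveat of Adam is
worth recording: its update rescales gradients by their running RMS, so on
an exactly-solved task even round-off-level gradients (~1e-12) grow into
learning-rate-sized steps.  The identity-preservation property is
therefore stated and tested under plain SGD, where updates are
proportional to the (vanishing) gradients.

Divergence (non-finite loss) raises an error carrying the epoch index.

## Metrics

All metrics compare magnitude images; the reconstruction pipeline itself
stays complex throughout.

* **NMSE** = ‖ref − est‖² / ‖ref‖² on the complex difference; invariant to
  joint rescaling.
* **PSNR** = 10 log₁₀(peak² / MSE), peak = max |ref|; an exact
  reconstruction is flagged infinite.
* **SSIM**: Gaussian-weighted sliding window, σ = 1.5 (truncated at 3.5σ,
  i.e. the conventional 11×11 support), K₁ = 0.01, K₂ = 0.03, population
  moments, dynamic range taken from the reference magnitude; the local map
  is averaged after cropping the half-window border.  The implementation
  is independent and cross-checked against scikit-image to 1e-6 (observed:
  identical to ~1e-16).

`evaluate_grid` draws a fresh seeded mask and noise stream per held-out
image (so the grid measures the method, not one mask realization), shares
the acquisitions across methods at each R, and emits one row of mean
metrics per method × acceleration.

## Study configuration and an observed metric trade-off

The default `ExperimentConfig` — the package's study conditions — is 50
random-ellipse 64×64 training phantoms and 20 held-out ones, noiseless
acquisitions at R = 2, 4, 6, per-sample masks, both CNN variants trained
separately for 30 epochs (≈210 Adam steps) per R.  These sizes keep the
full grid a few minutes on one core while leaving the qualitative behavior
stable across seeds.

Observed, reproducibly: the trained CNN_DC beats CNN_NDC and the
zero-filled baseline in PSNR and NMSE at every acceleration, both variants
beat the baseline in SSIM, quality degrades monotonically with R for every
method — and at R = 4 and 6 CNN_NDC scores *higher SSIM* than CNN_DC
despite clearly worse PSNR/NMSE.  The mechanism: a capacity-limited CNN
de-aliases by smoothing, and its reconstruction error resembles uniform
blur; the DC layer restores exact values on the few sampled
high-frequency lines, which lowers the error energy but changes its
character to structured stripes.  SSIM penalizes structured residuals far
more than blur, especially over the phantoms' large exactly-zero
background where any induced local variance is compared against none.  At
R = 2 enough lines are sampled that the effect disappears and CNN_DC leads
on all three metrics.  This is a genuine property of small de-aliasers
with hard data consistency on piecewise-constant test objects, not an
implementation artifact (the DC layer and SSIM are both verified against
independent oracles); on real-anatomy data with noisy backgrounds, DC
variants are commonly reported to lead in SSIM as well.

## Agreement statistics

Cohen's kappa is computed from the k×k contingency table as
(p_o − p_e)/(1 − p_e); it is 1 exactly on diagonal tables, 0 on tables
whose counts equal the outer product of their margins, and undefined
(returned as NaN) when both raters use a single category.  Interpretation
bands: 0.41–0.60 moderate, 0.61–0.80 good, 0.81–1.00 very good; values
below 0.41 are reported as "below moderate".  The χ² test is Pearson's,
without continuity correction by default (available as a flag); tables
with a zero expected count are rejected with guidance rather than
silently approximated.  A seeded generator simulates paired ratings with a
configurable true-agreement probability; under independent uniform
ratings of 30 patients, the empirical type-I rate of the 5%-level test
over 10,000 tables (restricted to tables with all expected counts ≥ 5) is
4.1–4.8% depending on seed — nominal up to the discreteness of small-n
tables.

## Numerical choices

* float64 for all operator math; float32 for network training (see above).
* Adam ε = 1e-8, β = (0.9, 0.999); He init std √(2/(k²·c_in)).
* DC treats λ = 0 and the unsampled set as exact pass-through (no division).
* SSIM rejects images smaller than the 11×11 window; NMSE rejects an
  all-zero reference; PSNR flags zero-MSE as infinite rather than raising.
* The dense DC oracle refuses images with more than 256 pixels — it exists
  to verify the closed form, not to reconstruct.
* Mask generation rejects R < 1, center_fraction outside [0, 1), and
  configurations whose line budget is exhausted by the central band.

## Limitations

* The 3-layer network is deliberately small; it under-fits at high
  acceleration, which is what exposes the SSIM/L2 trade-off above.
* Single 2D slices only; no 3D, non-Cartesian, or parallel-imaging
  calibration (SENSE/GRAPPA).
* λ is a fixed configuration value, not learned; one CNN + one DC layer,
  no cascades.
* Phantom backgrounds are exactly zero and intensities piecewise constant;
  SSIM values are therefore not comparable in absolute terms to values on
  clinical images.
* The agreement module treats tables as given; it does not model reader
  adjudication (e.g. a third reader breaking ties).
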