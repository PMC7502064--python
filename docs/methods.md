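# Methods

`octforce` models and calibrates a fiber-optic force sensor built into a
needle tip: a brass piston slides inside a sleeve, an epoxy layer between tip
and sleeve acts as a spring, and a spectral-domain OCT system watches the
piston across an air gap of about 1 mm. Axial force compresses the spring,
the gap shrinks, and the interferometric fringe recorded by the spectrometer
changes accordingly. The package provides (i) a physics-based simulator of
the raw spectral signal paired with ground-truth forces, (ii) the standard
six-step A-scan reconstruction, and (iii) 1D-convolutional ResNet regressors
calibrated to map either the raw interferogram or the reconstructed depth
profile to force, plus the harness that compares the two input
representations.

## Forward signal model

The spring is Hookean with a hard stop: the gap under force `F` is

    g(F) = max(g0 - F / k_s,  g0 - d_max)

with rest gap `g0` (default 1.0 mm), spring constant `k_s` (default 10/3
N/mm, so the calibrated 0–1 N range sweeps 0.3 mm of travel) and maximum
piston travel `d_max` (default 0.5 mm, i.e. saturation only beyond the
calibrated range, at 1.67 N).

The spectrometer records, at each of 1024 detector pixels with wavenumber
`k_i`, the two-beam interference of the fiber-end reference reflection with
the piston-face reflection:

    I(k_i) = p(t) * S(k_i) * (1 + 2 r_eff(g) cos(2 k_i g)) + eps_i

* `S` — Gaussian broadband-source envelope (peak 1000 counts, sigma 200 px
  over the 1024 pixels, plus a small floor so every pixel is illuminated).
  The DC term dominates the raw signal, as in real spectral-domain OCT.
* `r_eff(g) = r / (1 + (g / L_c)^2)` — effective fringe visibility. `r` is
  the piston reflectivity (default 0.3) and `L_c` a recoupling length
  (default 1.2 mm): light diverging from the fiber is recollected less
  efficiently the farther the piston sits, so fringe contrast grows as the
  gap closes. Setting `coupling_length=None` removes the effect and makes
  amplitude force-independent; the comparison experiment uses that switch.
* `eps_i` — i.i.d. Gaussian detector noise (default sd 5 counts), and
  `p(t)` an optional slow sinusoidal source-power drift (default off in the
  simulator's noiseless configurations, 1%/2 s when enabled) that gives the
  DC tracker something to follow.
* Autocorrelation and multiple-reflection terms are omitted: the needle has
  a single dominant reflecting surface.

The default wavenumber axis is centred at 4797/mm (a 1310 nm source) with a
mean pixel spacing of 0.15/mm: ~42 nm of optical bandwidth, a single-sided
imaging range of ~10.5 mm over 512 depth bins, and the piston surface at
depth bins ~34–49 across the force range. The chirped variant warps the
uniform grid by a monotone quadratic (`u + a u(1-u)`, default `a = 0.15`),
standing in for an uncalibrated spectrometer; dechirping resamples back to
the uniform span.

The acquisition protocol mimics a stepper-motor rig pressing the needle
against a plate: triangular ramp/release cycles between 0 N and a jittered
peak near 1 N (10% jitter), 1 kHz sampling, 2 mN force-sensor noise, all
values clipped to the calibrated [0, 1] N. One cycle spans ~2000 samples by
default, so successive scans are strongly correlated in force but their
fringe phases decorrelate (the carrier 2 k0 dg per scan is ~1–3 rad), which
is exactly the regime the EMA DC estimator needs.

## Reconstruction

Per scan, in acquisition order:

1. dechirp — linear interpolation onto the uniform wavenumber grid spanning
   the chirp map (identity for uniform maps);
2. DC estimation — exponential moving average across scans with damping
   `d = 0.05`, initialized to the first scan;
3. DC subtraction (update-then-subtract: the estimate includes the current
   scan);
4. apodization — symmetric 1024-point Hann window;
5. unnormalized FFT;
6. magnitude of bins 0–511.

Consequences worth knowing:

* The first A-scan is exactly zero (its own spectrum initializes the DC
  estimate). A burn-in of 200 scans (4/d) is discarded before training.
* A perfectly static reflector fades: with a constant gap the fringe is
  absorbed into the DC estimate and the peak decays geometrically. This is
  faithful EMA fixed-pattern-removal behaviour; the moving-ramp protocol
  avoids it except exactly at ramp vertices.
* Because scan-to-scan fringe phases decorrelate, the converged DC estimate
  carries a residual fringe memory of relative amplitude ~sqrt(d/(2-d)) ≈
  0.16, which perturbs A-scan magnitudes by a few percent. This is the
  dominant "noise" on reconstructed data even in noiseless simulations.
* `peak_depth` locates the piston classically: argmax over bins >= a guard
  band (default 4, excluding residual DC), ties toward the lower index,
  refined by a three-point parabolic fit. On noiseless ramps the inverted
  force (peak bin -> gap -> Hooke's law) is accurate to ~2.5 mN, well under
  the one-bin force equivalent of ~68 mN.
* The `narrow` window option (Gaussian, sigma 24 px) is a deliberately
  destructive apodization that collapses depth resolution; it exists for the
  information-loss experiment, not for production use.

## Models

`ResNetForceRegressor` wraps a numpy implementation of the 1D ResNet family
(convolutions, batch normalization, ReLU, max/global-average pooling,
residual blocks, Adam) with hand-written reverse-mode gradients, verified
against central differences in the test suite. The 2D architectures are
adapted by replacing every 2D convolution/pooling with its 1D counterpart at
the same kernel size and stride, and the classification head by a
single-output linear layer after global average pooling.

`resnet6` is the small variant: a stride-2 stem convolution (kernel 7),
max-pool, one identity residual block, one stride-2 projection block, GAP,
linear head — six convolutional layers counting the stem, the four block
convolutions and the 1x1 projection shortcut. Whether a projection counts
toward such a total is convention; ours is fixed and auditable via
`conv_layer_count()`. `resnet18`/`resnet34` follow the canonical
[2,2,2,2]/[3,4,6,3] basic-block layouts. The stem width is a free multiplier
(64 is the canonical default; desk-scale experiments use 8–16).

Input handling: reconstructed profiles are log-compressed (`log1p`) — the
conventional dynamic-range compression for OCT intensity data, which also
conditions the regression (raw magnitudes span ~5 decades and concentrate
gradient flow in a few depth bins). Both representations are then
standardized by a global scalar mean/std fitted on the training split only.
Targets stay in newtons.

Training: Adam (betas 0.9/0.999, eps 1e-8), batch MSE loss, fixed epoch
count, no schedule, no early stopping, last-epoch model. Two default-on
stabilizers compensate for the fact that at a fixed learning rate of 0.005
Adam's iterates never stop moving:

* tail averaging — the weights are Polyak-averaged over the final epoch's
  optimizer steps;
* BN recalibration — inference statistics are recomputed over the training
  set against the final weights (equal-weight averaging, one deterministic
  pass), removing the lag of exponential running averages.

Neither touches validation data, so no model selection is introduced. Both
are plain constructor flags.

## Experiment protocol

The full-scale protocol is 150 epochs, batch 128, learning rate 0.005, 20%
hold-out, five seeds, reporting validation MAE in mN (mean ± std over
seeds) per architecture and input representation, with the per-architecture
relative difference `(MAE_raw - MAE_recon) / MAE_recon`.

The hold-out defaults to the *final contiguous 20%* of the time series
(`block`): M-scan neighbours are near-duplicates, so a random split leaks
and flatters both arms. `random` is available for parity runs. Each seed
reseeds weights, shuffling and (for random splits) the split itself.

Desk-scale defaults, chosen once as this package's CPU-scale configuration:

* calibration recovery — 20,000 noiseless pairs, uniform chirp, ResNet6
  with stem width 16, 20 epochs, block hold-out. The recovered validation
  MAE sits at or below the ~10 mN (0.01 N) accuracy regarded as sufficient
  to discriminate tissue types from tip forces.
* raw-vs-recon comparison — 6,000 pairs, stem width 8, 8 epochs. To study
  information loss in reconstruction, the dataset disables the
  gap-dependent amplitude cue (`coupling_length=None`) and reconstruction
  uses the destructive `narrow` window: the raw arm keeps the fringe
  frequency intact while the recon arm sees a smeared peak, and the raw
  model wins — the directional analogue of learning from raw data
  outperforming reconstructed input.

Inference latency is reported as the median per-scan wall-clock time over
repeated batches, informational only.

## What the simulator does and does not show

The generator reproduces the features that make this calibration problem
what it is: a dominant DC envelope, a single moving fringe, chirped
sampling, temporally correlated ramp profiles, detector noise, and the
EMA's residual fringe memory. It does not model polarization, dispersion,
phase noise of the source, tissue scattering, lateral force components, tip
tilt, temperature drift of the epoxy spring, or the detector's true noise
statistics — all unknown for the real rig. Passing tests therefore
demonstrate that the pipeline and models behave correctly under the stated
physics, not that the absolute MAEs of any particular physical needle are
reproduced; the measured datasets behind the published per-needle numbers
are not public, and no claim is made about them.

## Numerical choices and degenerate inputs

* Reconstruction runs in float64; model training in float32 (BLAS
  throughput), gradient checks in float64.
* Hann window uses the symmetric N−1 denominator; FFT is unnormalized
  (intensities are arbitrary units throughout).
* `peak_depth` returns `None` for an all-zero profile; parabolic refinement
  only applies at strict interior maxima.
* Normalization scale is floored at 1e-8 with a warning for (near-)constant
  inputs.
* Training aborts with a diagnostic on a non-finite loss.
* All stochastic operations take explicit seeds; on fixed hardware the full
  simulate → reconstruct → train → evaluate pipeline is bit-reproducible.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; the full 150-epoch
  / width-64 / 180k-pair configuration is expressible but impractical on one
  CPU — the desk-scale defaults above are the supported regime.
* The spring constant, gap travel, reflectivity, recoupling length, noise
  levels and chirp of the real device are unpublished; all are config
  parameters with physically plausible defaults, not measured values.
* At a fixed learning rate the last-epoch model without tail averaging
  fluctuates by tens of mN between epochs; disable
  `average_final_epoch`/`bn_recalibrate` only if you want to study that
  effect.
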