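# Methods

This note records the models, conventions and numerical choices behind
`cardiomech`, including the points where the underlying procedures are
commonly left unspecified and this package had to fix a convention.

## Frame-difference contractility

The motion trace is the spatial mean of |I_k − I_{k−1}| over each
consecutive frame pair (optionally restricted to a ROI), so a video of n
frames yields n−1 samples. No smoothing is applied before differencing:
the method's sensitivity to sub-resolution motion comes precisely from
working on raw intensity fluctuations, and any blur would suppress it.

**Baseline.** Pixel noise gives |ΔI| a positive offset (for Gaussian noise
of sd σ the offset is 2σ/√π), and slow drift adds a tilt. The baseline is
removed with an ordinary-least-squares line fitted to the quiescent
samples — those at or below the trace median — and re-fitted once on the
residual's own below-median samples (two passes). Fitting the whole trace
would let contraction peaks bias the line.

**Events.** A motion period is one maximal contiguous run of samples
strictly above the threshold (default 0.1, in the trace's native intensity
units; the appropriate absolute value depends on the acquisition scale and
is a parameter). Under this rule a contraction–relaxation doublet whose
trace dips below threshold between the two bursts counts as two events;
`merge_gap` (seconds, default 0) can fuse runs separated by short
sub-threshold gaps, and `summarize_contractility(events_per_beat=2)`
reports doublets/min instead of runs/min. Width is the run duration, the
amplitude its maximum, SEM = sd/√n (NaN for a single event).

**Synchrony.** Per-ROI traces (disjoint ROIs required) are
baseline-corrected and cross-correlated with normalisation over the
overlapping segments; the lag is the argmax over shifts up to `max_lag`
(default 0.5 s) at frame resolution, positive when the second ROI starts
later, and the matrix is antisymmetric by construction. Because beat trains
are periodic, the correlation is too; `max_lag` must stay below half the
beat period or the maximum is ambiguous. No sub-frame interpolation is
attempted — at 25 fps the resolution is 40 ms, adequate for the
hundreds-of-milliseconds delays of interest.

## Hertz elasticity

The contact model is F = 4E√R δ^{3/2} / (3(1−ν²)) for a rigid sphere on an
elastic half-space, with ν = 0.5 (incompressible) by default and R the
probe radius (default 2.385 µm, a 4.77 µm silica bead). Positions are
assumed pre-converted to indentation axis (tip–sample separation); curve
files carry a `mode` header declaring this.

**Fitting.** The full approach segment is fitted with the piecewise model
"offset before contact, offset + Hertz beyond", by bounded
Levenberg–Marquardt/trust-region least squares over (E, contact point,
offset). Initialisation: contact point from the threshold-crossing
estimate (first run of 5 samples above baseline mean + 3 sd, baseline from
the first 25% of samples), offset from the pre-contact mean, E from the
closed form at the deepest point. The rms residual is taken over the whole
fitted segment. Non-convergence or an undetectable contact yields a fit
marked rejected rather than an exception, so batch processing never stops.

**Contact-point deviation.** The "deviation" quality measure needs a
reference; here it is defined as |least-squares contact point −
threshold-crossing estimate|. Curves where the two disagree by ≥ 100 nm are
rejected. This convention is a package choice and is deliberately
conservative: both estimators agree to within a few nm on clean curves.

**Quality gates.** Strict inequalities, applied in the order rms (25 pN) →
contact deviation (100 nm) → modulus range ((10², 10⁴) Pa, open interval);
each rejected curve is tagged with the first failing reason and the tally
always sums to the batch size. QC is applied per curve, before any pooling.
Group aggregation reports plain mean ± SEM per metadata-defined group (no
mixed-effect modelling; day-level random effects are out of scope, and the
report notes that group means here are unweighted rather than
least-squares means).

## Image quantification

- Li's minimum cross-entropy threshold comes from scikit-image; Huang's
  fuzzy threshold is implemented here over a 256-bin histogram (membership
  1/(1+|g−µ_side|/range), minimising the summed Shannon entropy of the
  membership). Both are deterministic, invariant to adding a constant and
  equivariant to positive scaling up to histogram quantisation.
- Connected components use 8-connectivity (diagonal neighbours join); the
  common interactive tools do not document their choice, so it is fixed
  here and exposed nowhere.
- Despeckling is a 3×3 median filter; 8-bit conversion is min–max scaling
  to [0, 255] with rounding. Both are explicit optional steps because they
  shift thresholds.
- The area-weighted mean fluorescence Σ A_i F̄_i / Σ A_i equals the plain
  pixel mean over the union of the patches whenever patch means are pixel
  means — this identity is the test oracle for the implementation.
- Mitochondrial networks split at 100 µm² with the boundary assigned to
  "small" (classes are "up to 100 µm²" and "above 100 µm²").
- The ratiometric (aggregate/monomer) image is defined only where the
  monomer signal exceeds a floor, defaulting to the monomer's Li threshold
  to keep near-zero denominators out. The mean ratio over the valid mask is
  NaN if the mask is empty. Note the pixelwise mean ratio is slightly
  biased upward under channel noise (E[A/M] > E[A]/E[M]); the bias decays
  quadratically with the noise level, which the tests check on a
  decreasing-noise ladder.
- Band spacing: the dominant band orientation comes from the mean structure
  tensor of the image gradients; intensities are projected onto the band
  normal, binned at 1 px, and the spacing is the mean peak-to-peak distance
  of the profile (≥ 3 peaks required) times the pixel size, ± SEM of the
  individual spacings.
- Densitometry: band/lane-total first (total protein from the membrane
  stain), then division by the reference group's mean per protein so the
  reference averages exactly 1; when the reference group is undetectable
  for a protein the declared fallback group is used and recorded per row.

## Synthetic data

The generators define the study conditions for all tests.

**Beating videos** default to 25 fps and 14-bit-scale intensities over a
128×128 field with background 100. Each cluster beats
`floor((duration − phase_delay)/beat_period)` times; a beat is a
contraction burst plus a relaxation burst `doublet_gap` (default 0.25 s)
later. A burst is a Gaussian-in-time envelope (sd `burst_sd` = 0.04 s, one
frame interval; truncated at ±3 sd); cluster pixels flip the perturbation
sign on alternate frames so the mean |ΔI| trace reproduces the envelope
exactly, without any random texture. The truth table records each burst's
FWHM frame span — the waveform of real contraction bursts is not specified
anywhere, so the half-maximum span is this package's truth convention. The
default amplitude (6 intensity units over a radius-15 px cluster, i.e. a
trace peak near 0.26 ≈ 2× the 0.1 threshold) was chosen so that a
threshold crossing at half the peak matches the FWHM, making detected
widths comparable to truth spans; pixel noise sd defaults to 0.5, giving a
post-correction trace noise ≈ 0.004, far below threshold. Imaging noise is
modelled as additive Gaussian — an assumption; real EMCCD noise is
Poisson–Gaussian, so absolute amplitudes on real data will scale
differently, and passing tests certify the analysis logic, not camera
physics.

**Force curves** sample 500 points from 0 to contact + max indentation
(default 0.5 µm, reaching ~1 nN at 1 kPa), with optional baseline offset,
tilt and Gaussian force noise (default 5 pN). The noiseless forward model
followed by `fit_hertz` recovers E to ~10⁻⁵ % — the forward/inverse
consistency every fit test builds on. No cantilever-deflection correction
or bottom-effect correction is modelled.

**Images** are background + objects (+ Gaussian noise), with exact pixel
areas and drawn means recorded; ratio pairs enforce the target
aggregate/monomer ratio pixelwise before noise; striation images are
sinusoidal with sub-Nyquist periods rejected.

All randomness flows from the single seed in each spec (no global state);
identical spec + seed is bit-identical.

## Statistics

Student's t (equal variance) is the two-group default, matching common
practice in this assay family; Welch is a flag. ANOVA + Tukey HSD
(statsmodels) handles ≥ 3 groups. Null calibration is verified by
simulation: t-test type-I error within [0.03, 0.07] and Tukey family-wise
error ≤ 0.07 at nominal α = 0.05 over 1000 replicates.

## Problem sizes and determinism

The acceptance script uses 200 noisy curves per condition, one 120 s
(3000-frame, 128×128) video per contractility condition, 100 random patch
sets, 200×200 threshold images and 1000-replicate null simulations — sizes
at which every stochastic check is stable across seeds while the whole run
stays light. All sub-streams derive from the single `--seed` argument.

## Known limitations

- The contractility threshold is scale-dependent; traces from different
  bit depths need rescaling or a re-chosen threshold.
- Lags are frame-quantised; delays below one frame interval are reported
  as 0 or one frame.
- The Hertz fit assumes a linear-elastic half-space: no viscoelasticity,
  no thin-sample correction, no tilt term in the fitted model (tilted
  baselines inflate the rms gate instead).
- The ratio image's mean is a mean of pixel quotients, not a quotient of
  means; the two differ under noise.
- Band spacing assumes a single dominant orientation; crossing striation
  systems in one field are not separated.
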