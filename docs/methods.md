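# Methods

This note documents the models, conventions and numerical choices
behind `fiberphot`. It is the authoritative description of what the
package computes; the README shows how to run it.

## The analysis problem

Fiber photometry records bulk fluorescence of a genetically encoded
dopamine sensor (e.g. dLight1.2) through an implanted optical fiber.
Two excitation wavelengths are interleaved: 465 nm drives the
ligand-sensitive fluorescence, and 405 nm sits at the sensor's
isosbestic point, where fluorescence is insensitive to dopamine
binding. The 405 nm channel therefore carries the nuisance processes —
fiber bending and tissue movement, photobleaching, slow drifts — but
none of the signal, and can be used to cancel those nuisances from the
465 nm channel.

The pipeline answers the question: *does dopamine release in the
recorded region change, time-locked to a behavioral event* (a social
sniffing bout, an elevated-plus-maze arm entry), and is that change
distinguishable from epochs sampled at random times?

## Preprocessing

1. **Low-pass filter.** Both channels are filtered at 3 Hz with a
   2nd-order Butterworth applied forward–backward
   (`scipy.signal.filtfilt`). Zero-phase filtering is a deliberate
   choice: a causal filter would delay transient onsets by tens of
   milliseconds and bias the peri-event latencies the analysis depends
   on. DC gain is exactly 1.
2. **Isosbestic scaling.** The 405 nm channel is scaled to the 465 nm
   channel by ordinary least squares over the *entire* recording
   (a single slope/intercept per session, not per epoch):
   fitted405 = a·f405 + b with (a, b) = argmin Σ(f465 − a·f405 − b)².
3. **ΔF/F0.** ΔF/F0 = (f465 − fitted405) / fitted405, elementwise.
   The denominator is guarded: every |fitted405| sample must exceed
   10⁻⁶ × median |fitted405|, otherwise the offending sample index is
   reported. Real fluorescence is strictly positive; only pathological
   synthetic input can trip this guard.

Any component of the 465 nm channel that is linearly predictable from
the control channel — shared motion, proportional bleaching — is
absorbed into fitted405 and divides out.

## Peri-event z-scoring

Epochs of ΔF/F0 are extracted from −1 to +3 s around each event onset
(onsets snapped to the nearest sample). Each epoch is standardized
against its own pre-onset baseline, the 1 s before t = 0:

    z(t) = (ΔF/F0(t) − μ_baseline) / σ_baseline

with the sample SD (n−1 denominator) of the baseline segment. Using
the per-event baseline SD — not a session-wide SD — is a convention
choice; it makes every retained epoch satisfy baseline mean = 0 and
baseline SD = 1 exactly, which the tests verify to 10⁻⁹. If a baseline
segment is degenerate (SD < 10⁻¹⁰), the session-wide ΔF/F0 SD is
substituted and the row is flagged.

Epochs whose window would cross a recording edge are dropped and
logged, never padded. Overlapping events are all retained.

z-traces are summarized as means over half-open per-second bins
[−1,0), [0,1), [1,2), [2,3); the onset sample belongs to [0,1). Bin
means are averaged per animal (unweighted over that animal's events,
pooled across sessions); the per-animal averages are the unit of all
repeated-measures statistics.

**Random-sampling null.** Twenty timestamps per session — ten uniform
in [5, 149.99] s, ten in [150, 294.99] s — are processed identically
to behavioral events. Stamps are drawn independently (collisions
allowed). This yields a control distribution with the same epoch
statistics but no behavioral time-locking.

## Inference

- **One-way RM ANOVA** on the subjects × bins matrix:
  F = MS_bins / MS_error with SS_error = SS_within − SS_subjects,
  df = (k−1), (k−1)(n−1). Sphericity is assumed (uncorrected), so the
  dfs are integers; a Greenhouse–Geisser option exists
  (`correction=True`) but is off by default. Note that the baseline
  bin has zero between-subject variance by construction (its mean is
  forced to 0 per event), a strong sphericity violation; the package's
  own calibration battery shows the uncorrected test's empirical
  type-I error at n = 10 remains near nominal (≈ 0.04–0.05 at
  α = 0.05) because the post-onset bins are positively correlated by
  the 3 Hz filter's autocorrelation.
- **Dunnett contrasts** compare every bin against the [−1,0) baseline
  bin via paired t statistics on per-subject differences. The
  multiplicity adjustment calibrates each |t| against the Monte Carlo
  null distribution of the maximum |t| over the same subjects × levels
  layout (10⁵ seeded draws, add-one smoothed, p resolution ≈ 10⁻⁵ in
  rank terms, ≈ 0.003 practically). The 95% quantile of max |t| gives
  simultaneous confidence intervals. `adjust="bonferroni"` provides
  the conservative closed form; Monte Carlo Dunnett p values are never
  larger.
- **Two-way RM interaction** for time × (signal vs random): fully
  within-subject decomposition, interaction tested against the
  subject × A × B residual. In the 2 × 2 case this equals the squared
  paired t on the per-subject difference of differences (verified
  numerically in the tests).
- **Unpaired two-tailed t test** (pooled variance, df = n₁ + n₂ − 2)
  for between-group comparisons such as anterior vs posterior fiber
  counts.
- α = 0.05 throughout.

All three tests are implemented from their sums of squares and
cross-checked in the test suite against independent references
(pingouin's RM ANOVA, scipy's t test) to 10⁻⁸ in the statistic.

## Imaging quantification

- **Automatic threshold**: Otsu's method on a 256-bin histogram of
  each channel (via scikit-image), with a brute-force between-class
  variance maximization as the test oracle.
- **Mander's coefficients**: thresholded form by default — M1 is the
  green intensity on pixels above *both* channels' thresholds divided
  by total green intensity above the green threshold; M2 symmetric.
  The classic (unthresholded) form is available with
  `thresholded=False`. The thresholded form was chosen because the
  workflow thresholds each image automatically before computing the
  coefficient; both forms coincide on clean, zero-background images.
- **ROI fiber counts**: supra-threshold pixel counts inside
  0.3 × 0.4 mm rectangles randomly allocated (seeded rejection
  sampling) within a region mask. Default scale is 1 px = 1 µm when no
  metadata is present; overridable.

## The synthetic-data generator

No recordings were published for this paradigm, so validation runs on
a generator that emulates the statistical structure of the recordings
with known ground truth. Channel model in volts:

    f465(t) = B₄₆₅ · bleach₄₆₅(t) · (1 + ΔF/F_true(t)) + g₄₆₅·m(t) + ε₄₆₅(t)
    f405(t) = B₄₀₅ · bleach₄₀₅(t)                      + g₄₀₅·m(t) + ε₄₀₅(t)

- **Transients**: difference-of-exponentials kernel
  (1 − e^(−t/τ_rise))·e^(−t/τ_decay), normalized to unit peak
  (peak at t* = τ_rise·ln(1 + τ_decay/τ_rise) ≈ 0.31 s at defaults
  τ_rise = 0.15 s, τ_decay = 1.0 s — second-scale kinetics typical of
  dLight-class sensors; no published kinetic fit exists for this
  preparation, so these are conventions). Event-locked transients get
  a non-negative latency jitter (half-normal, SD 0.2 s). Open-arm
  entries and social sniffing inject positive amplitudes; closed-arm
  entries inject the same magnitude negative.
- **Amplitude**: default 0.006 ΔF/F0, calibrated once so the
  grand-mean peri-event z peaks near 2 under the default noise and
  spontaneous-activity levels (measured 2.15 over 8 seeds). The
  familiar (habituated) day sets the event-locked amplitude to
  `habituated_amp` (default 0).
- **Spontaneous transients**: homogeneous Poisson process
  (0.05 events/s), same kernel, amplitudes uniform in
  [0.5, 1] × `spont_amp`. `spont_amp` is deliberately a separate
  parameter (default equal to the default event amplitude) so
  habituated sessions keep spontaneous dopamine fluctuations while
  losing only the event-locked response — without this the null
  batteries would be unrealistically clean.
- **Bleaching**: multiplicative double-exponential droop
  (τ 30 s / 600 s, 0.1 V total per channel).
- **Motion**: one shared sub-1 Hz low-pass-filtered Gaussian trace,
  scaled to `motion_sd` (default 0.05 V) and injected into both
  channels with per-channel gains (defaults 1.0/1.0). Equal gains and
  equal bleach amplitudes make the nuisances proportional across
  channels — the regime the isosbestic regression is designed for.
- **Noise**: iid Gaussian per channel, 0.02 V.
- **Sessions**: 300 s at 240 Hz (the effective rate of 12 kHz
  acquisition decimated by 50). Events live in [5 s, duration − 3 s]
  with a 5 s minimum gap; 10 social bouts or 5 + 5 alternating EPM
  entries per session by default.
- **Determinism**: every generator is a pure function of
  (parameters, seed); per-animal seed = cohort seed + animal index.

What the generator does *not* emulate: lock-in modulation and
demodulation, photon shot noise, sensor saturation, hemodynamic
contamination, non-proportional channel artifacts, and behaviorally
correlated motion. Passing recovery tests therefore demonstrates that
the analysis chain is correct and well calibrated under its own
assumptions, not that those assumptions hold for any particular rig.

Image fixtures: punctum pairs are flat disks (green r = 3 px inside
red r = 5 px when colocalized) with all non-paired centers kept
mutually disjoint, so the constructed overlap fraction equals
round(f·n)/n exactly; fiber images are short bright strokes with a 3×
posterior density step.

## Validation batteries (`fiberphot.experiments`)

Replicate counts were sized to give stable rates in minutes on one
core: 20 cohorts of 10 animals for detection batteries, 500 cohorts
for the type-I error calibration, 5 seeds for image orderings.
`scripts/acceptance.py` runs all batteries from scratch and writes the
summary numbers as JSON.

## Known limitations

- The Dunnett Monte Carlo null assumes exchangeable iid normal scores
  within the layout; heavy-tailed per-animal summaries would make the
  adjustment approximate.
- The uncorrected RM ANOVA's size depends on the bin covariance
  structure the pipeline induces; with very short baselines or
  unfiltered data the sphericity violation could inflate it.
- The isosbestic correction is linear and whole-session; wavelength-
  dependent bleaching that changes the channel ratio over time would
  leave a residual (visible in the fit SSE).
- `simulate_fiber_image` uses abutting anterior/posterior half-images
  as a stand-in for two separate sections.
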