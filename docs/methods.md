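# Methods

## Signal model of the synthetic generator

The generator treats an LFP session as

    x(t) = n_beta(t) + sum_b A_b(t) · sin(2π f_b t + φ_b)

where `n_beta` is 1/f^β colored Gaussian noise (spectral shaping of
white noise in the frequency domain, renormalized to a target standard
deviation) and each band schedule `b` contributes a sinusoid at a fixed
in-band center frequency `f_b` with a random uniform phase and a
piecewise-constant amplitude envelope: `prestim_amplitude` outside the
stimulus phase of each trial, `stim_amplitude` between the probe-onset
and paw-withdrawal events, and zero in the noise-only padding between
trial epochs. Amplitude transitions are smoothed with a 100 ms
raised-cosine ramp so that band-power changes are attributable to the
schedule rather than to step-edge splatter.

Defaults encode the study conditions: 20 trials per session, 1 kHz
sampling, 5 s prestimulus, withdrawal latencies uniform on 2–8 s
(the probe ramp lasts 20 s, so latencies must stay below that), 5 s
poststimulus, 1.5 s inter-trial padding, β = 1 pink noise of unit
standard deviation, and a theta (6 Hz) schedule whose amplitude halves
during the stimulus phase (unit prestimulus amplitude). Amplitude units
are arbitrary and carried as metadata; only ratios matter to the dB
contrasts.

What this emulates — and what it does not: the generator reproduces the
*statistical* structure the analysis assumes (phase-locked band-power
changes on a 1/f background, seeded and stationary within phases). It
contains no biophysics, no movement or chewing artifacts, no
non-stationary drift, no volume conduction, and its oscillations are
pure tones rather than band-limited bursts. Passing tests therefore
demonstrate that the pipeline recovers designed effects under this
surrogate, not that any in vivo claim is reproduced.

Randomness: every generator derives independent child streams from its
master seed via `numpy.random.SeedSequence.spawn`, in a fixed documented
order (session: noise, latencies, phases; behavior: PWT, CPA), so
outputs are bit-reproducible and insertion-order independent. The
pipeline splits its master seed into session/behavior seeds with
`SeedSequence(seed).generate_state(2) % 2**31`.

## Behavioral calibration tables

The behavioral literature for this paradigm reports significance
patterns but no numeric group means, so the generator's default
PWT/CPA mean tables are synthetic calibration values (clearly labeled
as such in `synthetic.py`). They were chosen once to realize the
qualitative pattern the design implies — thresholds near 38 g at
baseline (instrument ceiling 50 g), collapse to ~16–20 g 4 h after the
first injury in the model and EA groups, EA recovering faster (28 vs
20 g at day 1), near-recovery by day 13, and a model-only relapse after
the day-14 contralateral injury (20 vs 34–38 g at day 15); CPA
pain-paired occupancy drops from ~900 s to ~600 s only for the model
group at day 15. Reading noise is 4 g SD with a subject intercept of
half that (both scale to zero with `pwt_sd`, so zero-noise designs
reproduce the means exactly); occupancies use an 80 s SD and are carved
from a ~1700 s total active time so compartment sums never exceed the
1800 s session.

## Spectral chain choices

* **Filter.** `butter(4, [2, 45], fs)` as second-order sections,
  applied with `sosfiltfilt` (odd signal extension at the edges,
  scipy's default pad length). Forward–backward application doubles the
  magnitude order and cancels phase; the analytic oracle used in tests
  is |H(f)|² of the same design, so the contract is self-consistent.
  The acquisition-side 0.3–250 Hz hardware filter is a property of the
  recording and is never re-applied.
* **Spectrogram.** 1024-sample Hann windows, 50% overlap, density
  scaling, no zero padding, trailing partial window dropped; bin
  spacing 1000/1024 ≈ 0.977 Hz; bins restricted to 2–45 Hz (44 bins).
  dB conversion is 10·log₁₀ of power with a 10⁻¹² floor, so an all-zero
  signal maps to exactly −120 dB.
* **Smoothing.** "Width 3" Gaussian smoothing is implemented as a
  3-point kernel along the frequency axis with σ = (width − 1)/5 bins
  (the `gausswin` convention of the MATLAB stack this analysis style
  comes from), zero-padded with edge renormalization to unit mass. A
  wider kernel (e.g. σ = 3 bins) was rejected because it smears a
  theta-band peak across the one-bin-wide delta band and destroys band
  selectivity; with the 3-point kernel a theta-confined amplitude
  change leaves neighbouring bands within ~0.5 dB. Smoothing is applied
  to the dB field (matching the stated order of operations), so kernel
  mass is conserved in dB, not in linear power.
* **Segmentation.** Half-open intervals throughout; spectrogram windows
  are assigned to a phase by window-center time. Stimulus phases too
  short to contain a window center are recomputed with a single window
  of the phase length rounded down to a power of two (minimum 256
  samples ≈ 0.256 s); shorter phases are dropped and logged. Trials
  with no recorded withdrawal get a stimulus window truncated at
  onset + 20 s (the probe ramp end) and are flagged. Trial exclusions
  are counted in the run manifest.
* **Band means** are arithmetic means of dB cells (after normalization
  and smoothing), i.e. averaging happens on the decibel scale, matching
  the stated pipeline order rather than the linear-power average a
  variance argument might prefer.

## Statistics

Both ANOVAs are computed from explicit sums of squares. The one-way
repeated-measures F uses the condition×subject interaction as error;
with two conditions it reduces to the squared paired t (verified to
1e-8 relative in tests, and against pingouin). The mixed design uses
subjects-within-groups for the between factor and
time×subjects-within-groups for the within factor and interaction;
under spherical Gaussian nulls its empirical type-I error is calibrated
to 0.03–0.07 at α = 0.05 over 1000 replicates. Group sizes may be
unequal (cell-count weighted sums of squares); time must be complete
within subject, and incomplete designs are rejected listing the missing
cells.

No sphericity correction is applied by default, matching the reporting
style this pipeline mirrors; Greenhouse–Geisser df scaling (epsilon from
the double-centered condition covariance) is available via
`correction="gg"`.

Post hoc policy: one-way — all pairwise paired t-tests, Bonferroni over
the number of pairs; mixed — pairwise group differences at each
timepoint against the pooled error term
(SS_subj_within + SS_err_within over their summed df), Bonferroni over
all contrasts performed. The session-level band report treats its six
prestimulus-vs-stimulus contrasts (broadband + five bands) as one
Bonferroni family, keeping the family-wise false-flag rate at the
nominal α; significance is strict (`p < α`).

## Problem sizes and numerical notes

Simulation-based checks use sizes chosen to make their Monte-Carlo
error small relative to the asserted bounds while keeping the default
suite quick: 100 replicate sessions of 20 trials for parameter-recovery
and selectivity, 1000 replicates for ANOVA type-I calibration
(binomial SE ≈ 0.7 percentage points at α = 5%), 200 replicates for
the behavioral power check, and 20 seeds for the end-to-end null
pipeline. F statistics at zero error mean squares return 0 (zero
numerator) or +inf; p-values come from `scipy.stats.f`. CSV stores
round floats through pandas' default repr (deterministic); the binary
LFP store is little-endian float32, so loads are bit-exact for
float32-representable data and the CSV dialect is exact to its six
printed decimals.

## Known limitations

* Single-channel only; no multi-channel arrays, no spike data, no
  coherence or phase measures.
* The dB-domain averaging and smoothing follow the mirrored pipeline's
  stated order; statistically minded users may prefer linear-power
  averaging, which this package intentionally does not do by default.
* The synthetic cohort satisfies compound symmetry, so the default
  (uncorrected) df are exact there; real repeated measures may violate
  sphericity and warrant `correction="gg"`.
* CPA occupancies are inputs; no video-tracking or trajectory analysis.
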