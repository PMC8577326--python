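# Methods

`neommr` implements a complete analysis chain for a neonatal auditory
mismatch-response (MMR) experiment that contrasts vowel-like and nonspeech
stimuli in a roving-standard oddball design, together with a forward
simulator that generates the multichannel EEG the chain consumes.  This
note documents the models, the conventions, the tunable parameters, and
the design decisions taken where the design was genuinely open.

## Stimuli

Nonspeech stimuli are inharmonic tone complexes: 15 sinusoidal components
on a geometric ladder starting at 500 Hz with ratio 1.15 (top component
≈ 3538 Hz), amplitude-weighted by a cascade of three second-order
resonators at the formant frequencies of the vowel each complex mimics
(nonfocal [ɛ]: 755/1646/2710 Hz; focal [a]: 864/1287/2831 Hz).  Durations
are 220 ms for the two spectral stimuli and 180/360 ms for the short/long
durational pair; amplitude is ramped linearly over 5 ms at both edges and
RMS is equated across the set (relative tolerance 1e−6).

Open parameters and how they were fixed:

* **Formant bandwidths** are not part of the stimulus description we work
  from; defaults are 90/110/170 Hz, typical vocal-tract values, and
  configurable on `FormantSpec`.
* **Component phases** default to zero (deterministic synthesis);
  seed-driven random phases are available.
* The resonance shaping is applied as an amplitude weight on each
  component (the resonator magnitude evaluated at the component
  frequency) rather than by time-domain filtering.  For a sum of
  stationary sinusoids the two are identical in magnitude; the weighting
  form is deterministic and trivially testable.
* **Speech-analogue tokens** are synthetic stand-ins used only to give the
  simulator a consonant–vowel timing structure: a 150 ms noise prefix (the
  "fricative") followed by a harmonic source shaped by the same formants.
  They make no claim of acoustical fidelity to natural recorded syllables.

Formant recovery (`estimate_formant_peaks`) uses autocorrelation-method
LPC at 8 kHz with order 6 and 0.97 pre-emphasis, returning the local
maxima of the all-pole envelope.  Order 6 (one pole pair per expected
formant) is deliberate: higher orders lock onto individual source
components of the inharmonic ladder instead of the envelope.  With the
default synthesis the nonfocal complex's three envelope peaks land within
5 % of the specified centers.  The focal complex's F3 (2831 Hz) sits
between two widely spaced ladder components and is recovered less
accurately; F1 and F2, which carry the focal/nonfocal distinction, are
within 5 %.

## Paradigm

A block = 8 warm-up tokens of type A, then trains of identical stimuli
alternating between the two types, 100 trains per type, train lengths
4–8 each occurring exactly 20 times per type (shuffled per seed,
independently per type).  Token counts are therefore 608 (type A,
including warm-up) + 600 (type B) = 1208; at a stimulus-onset asynchrony
of 1.09 s a block lasts 21.95 min.  The first post-warm-up train is type
B, so the warm-up functions as the opening type-A run.

Roles: the first token of each train is the *deviant*, the last two are
*standards*, and every non-train-initial token enters the sensory-ERP
average.  Whether the warm-up's final tokens should count as standards is
ambiguous; we take the conservative reading — the warm-up contributes
neither deviants nor standards, its tokens 2–8 count toward sensory
averages only (`BlockConfig.warmup_in_sensory`).

## Forward model (synthetic data generator)

Six channels (F3, FZ, F4, C3, CZ, C4; nose reference as metadata), 3000 Hz.
Each token adds a sensory kernel: a Gaussian onset component (peak 300 ms
after vowel/tone onset, SD 60 ms) plus a Gaussian offset component (peak
350 ms after stimulus offset), so duration differences shift the offset
component by exactly the duration difference.  Deviant tokens additionally
receive half-sine MMR deflections spanning the early (80–220 ms) and late
(500–700 ms) post-change-onset windows.

**Amplitude convention.** Every amplitude parameter is the *mean amplitude
over its scoring window* (µV), so the injected AUC over that window is
exactly `amplitude × window width` — an analytic ground truth for the
measures stage.

Default effect sizes are anchored to the magnitude of newborn ERP/MMR
studies of this kind: onset response 0.45 µV (≈ 90 µV·ms over the 200 ms
window) with a ×1.7 speech gain; an [ɛ]-vs-[a] onset difference of
0.27 µV at central channels and a duration-coded offset effect of 0.29 µV
per unit code at midline, both speech-only; an MMR base deflection of
0.19 µV (early) / 0.04 µV (late) on all deviants; and a from-E-negative
asymmetry of −0.64 µV (early) / −0.88 µV (late) applied with region
weights left 1.0 / midline 0.6 / right 0.0, speech-only.  Subject
heterogeneity enters as a Gaussian multiplier on kernel amplitudes
(SD 0.2) and an additive per-infant offset on MMR deflection amplitude
(SD 0.45 µV), shared across an infant's blocks.

Background noise is spatially correlated 1/f noise (power exponent 1.0,
channel correlation 0.5), band-limited to the 0.3–100 Hz amplifier band by
zero-phase filtering (the kernels are already smooth), scaled to
15 µV RMS.  The RMS was chosen so that the ±90 µV rejection threshold is
crossed essentially only by the artifact process, not by background noise
(measured noise-only rejection < 0.1 %): rejection-rate checks then
calibrate against the artifact rate alone.  Artifacts are Hanning pulses
(50 ms, ±300 µV peak) injected on a Bernoulli subset of tokens
(rate 0.25) and confined to 50–850 ms post token onset so that each pulse
contaminates exactly one epoch despite the 10 ms overlap of consecutive
epochs.

What the generator does *not* emulate: biophysical head geometry, neonatal
sleep-stage dynamics, non-stationary noise, slow drifts and electrode
artifacts other than the pulse model, or latency jitter of the evoked
components.  Passing tests therefore demonstrate the correctness and
calibration of the *analysis chain*, not the physiological realism of the
input.

## Preprocessing

* 40 Hz low-pass: symmetric FIR (Hamming, transition 40→48 Hz) applied
  centred, hence zero-phase; stopband ≥ 53 dB above 48 Hz, passband ripple
  < 0.1 dB.  This doubles as the anti-alias filter for the 10× decimation
  to 300 Hz.
* Epochs are **vowel/tone-onset-locked**: [−100, 1000) ms half-open on the
  300 Hz grid, exactly 330 samples, with the [−100, 0) ms mean subtracted
  per epoch and channel.  For speech tokens the lock point is 150 ms after
  token onset (the vowel begins after the consonantal prefix).  This
  convention is what lets every analysis window — including the late MMR
  window of the durational speech contrast, which ends 1030 ms after
  *token* onset — fit inside the epoch.
* Rejection: an epoch is discarded when |amplitude| ≥ 90 µV on *any*
  channel (the any-channel rule; per-channel counts are logged).
* Plus/minus SNR: signal = plain average; noise = average with alternating
  epoch signs; SNR = RMS(signal)/RMS(noise) over 0–1000 ms pooled across
  channels (amplitude ratio, not power).  An odd epoch count keeps the
  last epoch with a + sign in both averages.  Sensory ERPs with SNR
  strictly below 1 are excluded from the sensory statistics only; the MMR
  stage computes its own averages.  Zero noise RMS (noise-free simulation)
  reports +inf.
* Savitzky–Golay smoothing (order 1, 21 samples) is applied to averages
  before area measures; on interior samples this equals a 21-point moving
  average.

## Measures

Windows (all 200 ms wide for sensory, 140/200 ms for MMR): onset
200–400 ms post vowel/tone onset; offset 250–450 ms post stimulus offset
(i.e. 470–670 / 430–630 / 610–810 ms post vowel onset for the
220/180/360 ms stimuli); early MMR 80–220 ms and late MMR 500–700 ms post
*change onset* — vowel/tone onset for spectral deviations, short-stimulus
offset (+180 ms) for durational ones.

AUC is the signed trapezoidal integral (µV·ms); window edges snap to the
nearest 300 Hz grid point (≤ half a sample) and both snapped endpoints
enter the quadrature.  Signed (not rectified) area is used because
negative-going mismatch responses are themselves meaningful (a mismatch
*negativity*).  Difference waves are deviant-minus-standard for the *same
physical stimulus* (enforced), channels are pooled into laterality regions
(F3&C3, FZ&CZ, F4&C4) by averaging — by linearity of the integral,
pooling waveforms before integrating equals averaging per-channel AUCs.

## Statistics

One mixed model per response window on the per-subject cell AUC table,
with sum-to-zero contrast codes: Domain −0.5/+0.5 (speech/nonspeech),
Spectrum −0.5/+0.5 ([a]/[ɛ-family]), Dimension −0.5/+0.5
(duration/spectrum), Deviant −0.5/+0.5 (to-E/from-E), Duration codes
+1/−0.2/−0.6 for 360/220/180 ms (used verbatim; it is not an affine map of
milliseconds and no re-derivation is attempted), LateralityA
−0.25/−0.25/+0.5 (left/right/midline), LateralityB −0.5/+0.5 (left/right),
Anteriority −0.5/+0.5 (central/frontal).  Interaction columns are products
of constituent codes.  Random effects: per-subject intercepts plus slopes
(Spectrum for onset; Spectrum and Duration for offset; Dimension, Deviant
and their interaction for MMR).

Estimation is REML through `statsmodels` `MixedLM` (cross-checked against
`lme4` on identical designs to ~1e−15 relative agreement); singular
random-effects fits are flagged on the results object, not fatal.  Cell
means are fixed-effect predictions at the cell's code vector with random
effects at zero; SE = √(xᵀVx) with V the fixed-effect covariance — the
marginal-prediction convention, under which cell SEs vary across cells.

Two cell means are compared by **mutual CI exclusion**: exclusive at a
level iff each mean lies outside the other's interval, with multipliers
1.96 (95 %) and 1.645 (90 %) exactly.  95 %-exclusivity implies
90 %-exclusivity.  No multiple-testing correction is applied beyond this
two-level rule, mirroring the analysis convention the package implements.
A cell is "reliably negative" when mean + 1.96·SE < 0.

## Parameter-recovery experiment

`neommr.experiments` asks whether the full chain recovers an injected
left-lateralized, from-E-negative durational asymmetry, and whether the
CI-exclusion rule is calibrated under the null.  Problem sizes are scaled
to desk hardware: 50 replicates × 20 subjects per arm, only the speech
durational block per subject, 2 occurrences per train length (10 trains
per type) and simulation directly at the 300 Hz analysis rate; the
preprocessing chain is unchanged.

Calibration constants, fixed a priori from null cohorts: the epoch-noise
within-cell SD of the left-region early-MMR AUC in this design is
≈ 800 µV·ms (≈ 8 deviant epochs survive rejection per subject and cell).
The experiment sets the between-infant mismatch-responsiveness SD equal to
that value and injects an asymmetry of 1.2 × the resulting total
within-cell SD (√2 × 800 µV·ms).  Two properties follow analytically and
are verified empirically: (i) power for the 95 % mutual-exclusion flag at
n = 20 is ≈ 99 %, and (ii) because both deviant cells share the subject
offset, the cell SEs include variance that cancels in the difference,
making mutual exclusion conservative under the null (≈ 5 %, comfortably
below 10 %).  If between-subject variance were negligible instead, the
mutual-exclusion rule would be anticonservative (≈ 16 % at the "95 %"
level) — a known property of interval-overlap testing that this design
documents rather than hides.

## Numerical conventions and degenerate inputs

* Epoch count conservation (events → epochs → kept → averaged) is logged
  and asserted at every pipeline hand-off.
* Empty conditions (e.g. artifact rate 1.0) yield flagged-empty averages
  and skipped model fits recorded in the QC report, not exceptions; a
  rank-deficient design raises in the stats layer with the aliased columns
  named, and the pipeline records such fits as skipped when upstream
  gating (not user error) caused the degeneracy.
* All randomness flows from explicit seeds; per-subject streams derive
  from a master seed via `SeedSequence.spawn`, and an infant's random
  effects are shared across their blocks.
* EDF export uses 16-bit integers with per-channel symmetric physical
  ranges (quantization ≤ 2·max|x|/65535 µV); events and roles travel in a
  CSV sidecar that round-trips exactly.

## Known limitations

* The focal complex's F3 is recovered only approximately by the all-pole
  envelope (see Stimuli).
* MixedLM degrees of freedom are normal-approximation (z) rather than
  Satterthwaite; coefficient p-values on small cohorts are accordingly
  approximate.  Cell means and SEs, which drive the CI rule, do not
  depend on the df approximation.
* The speech-analogue stimuli and the noise model are simulation devices;
  no claim is made that conclusions about real infant recordings follow
  from simulated calibration alone.
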