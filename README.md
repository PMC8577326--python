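# neommr

A reusable, tested analysis pipeline for **neonatal auditory mismatch-response
(MMR) experiments** in the roving-standard oddball design, plus a forward EEG
simulator so every stage can be exercised without access to infant recordings.

The scientific setting: sleeping newborns hear trains of identical sounds that
alternate between two stimulus types — vowel-like speech tokens ([fɛ], [fa],
[fɛː]) or matched inharmonic tone complexes — so that each physical stimulus
serves both as a *standard* (end of a train) and as a *deviant* (first token
of a train).  Sensory event-related potentials (ERPs) index acoustic
processing; the deviant-minus-standard difference wave (the MMR) indexes
memory-based change detection, and its polarity and lateralization carry
developmental meaning.  The package covers:

* **stimuli** — inharmonic tone complexes (15 components, 500 Hz × 1.15ᵏ)
  shaped by three-formant resonance envelopes; linear ramps, RMS equating,
  WAV export, and LPC-based formant verification.
* **paradigm** — roving-standard blocks: 8 warm-up tokens + 100 trains per
  type with train lengths 4–8 each occurring exactly 20 times (1208 tokens,
  SOA 1.09 s, ≈ 22 min), with deviant/standard/sensory role labelling.
* **simulate** — a forward model: Gaussian onset/offset ERP kernels,
  half-sine MMR deflections on deviants (with configurable lateralized
  directional asymmetries), correlated 1/f noise in the 0.3–100 Hz amplifier
  band, and high-amplitude artifact pulses; 6 channels at 3000 Hz.
* **preprocess** — zero-phase 40 Hz low-pass, decimation to 300 Hz,
  vowel/tone-locked [−100, 1000) ms epochs with baseline correction, ±90 µV
  rejection, condition averaging, plus/minus SNR gating, Savitzky–Golay
  smoothing.
* **measures** — signed area under the curve (µV·ms) in onset/offset and
  early/late MMR windows, change-onset bookkeeping, difference waves,
  laterality-region pooling.
* **stats** — linear mixed models (REML) on the AUC tables with the study's
  contrast codes, statsmodels-style `AucMixedModel` → `fit()` →
  `AucMixedModelResults` with cell means, x′Vx standard errors, and the
  95 %/90 % confidence-interval mutual-exclusion rule.

At the core of the statistics is the comparison of modelled cell means
m̂ ± SE: two cells are *mutually exclusive* at level α iff each mean lies
outside the other's interval m̂ ± z·SE (z = 1.96 at 95 %, 1.645 at 90 %), and
a response is a reliable mismatch *negativity* when m̂ + 1.96·SE < 0.

## Worked example

Simulate a small cohort (4 infants per domain, shortened blocks), run the
whole chain, and inspect the early-MMR cell means:

```python
from neommr.io import PipelineConfig
from neommr.pipeline import run_pipeline

cfg = PipelineConfig(n_subjects_per_domain=4, occurrences_per_length=2,
                     master_seed=7)
bundle = run_pipeline(cfg, outdir="demo_out")
cells = bundle["fits"]["early_mmr"].compare_deviants()
print(cells[(cells.domain == "speech") & (cells.dimension == "durational")])
```

prints (one row per deviant cell; `mark` would show `**`/`*` for cell pairs
mutually exclusive at 95 %/90 %):

```
domain  dimension  region deviant       mean         se mark  negative_95
speech durational    left    to_E 164.127817 407.265080             False
speech durational    left  from_E 175.968737 325.194091             False
speech durational midline    to_E 224.393531 407.265080             False
speech durational midline  from_E 354.324351 325.194091             False
speech durational   right    to_E 558.985793 407.265080             False
speech durational   right  from_E 179.593544 325.194091             False
```

`mean` and `se` are model-predicted AUCs in µV·ms for each deviant direction
and scalp region.  At this miniature scale no contrast is flagged — the
default injected asymmetry is realistic (tens of µV·ms) while a 4-infant
cohort resolves only far larger effects; the package's recovery experiment
(`neommr.experiments`, 50 replicates × 20 infants) shows the left-region
flag appearing reliably once the asymmetry reaches one within-cell SD.
The QC report (`demo_out/qc.json`) records conservation counts per
recording, e.g.

```
{'subject': 'sp_S000', 'domain': 'speech', 'dimension': 'spectral',
 'events': 128, 'epochs': 128, 'kept': 106, 'rejected': 22}
```

A CLI mirrors the library (`neommr synth-stimuli | make-paradigm | simulate |
preprocess | measure | fit | run`), reading/writing WAV, EDF (+ CSV event
sidecars), CSV tables and YAML configs.

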