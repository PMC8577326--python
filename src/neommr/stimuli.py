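"""Synthesis of the auditory stimuli used in the roving-standard paradigm.

The nonspeech stimuli are inharmonic tone complexes: 15 sinusoidal components
on a geometric frequency ladder (500 Hz, ratio 1.15), amplitude-shaped by a
three-formant resonance envelope so that the complex carries the spectral
envelope of a vowel without being confusable with one.  Speech-analogue
tokens (for simulation only) reuse the same formant shaping with a harmonic
source and a noise prefix standing in for the initial fricative; they are
synthetic stand-ins, not re-recordings of natural syllables.

Formant sets follow the Czech vowels the complexes mimic:

* nonfocal [ɛ]: F1–F3 = 755, 1646, 2710 Hz (F1 and F2 spread apart)
* focal   [a]: F1–F3 = 864, 1287, 2831 Hz (F1 and F2 close together)

Durations are 220 ms (both spectral stimuli), 180 ms (short) and 360 ms
(long); amplitude is ramped linearly over 5 ms at onset and offset and RMS
is equated across the stimulus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz
from scipy.signal import resample_poly

__all__ = [
    "FormantSpec",
    "SourceSpec",
    "StimulusWaveform",
    "NONFOCAL_E",
    "FOCAL_A",
    "DEFAULT_SOURCE",
    "component_frequencies",
    "formant_envelope",
    "synthesize_inharmonic_complex",
    "synthesize_speech_analogue",
    "apply_linear_ramp",
    "equate_rms",
    "estimate_formant_peaks",
    "standard_stimulus_set",
    "write_wav",
]


@dataclass(frozen=True)
class FormantSpec:
    """Three formant center frequencies and bandwidths (Hz).

    Bandwidths are not part of the published stimulus description; the
    defaults 90/110/170 Hz are typical vocal-tract values and are
    configurable.
    """

    f1: float
    f2: float
    f3: float
    b1: float = 90.0
    b2: float = 110.0
    b3: float = 170.0

    def __post_init__(self) -> None:
        if not (0 < self.f1 < self.f2 < self.f3):
            raise ValueError(
                f"formants must satisfy 0 < f1 < f2 < f3, got "
                f"{self.f1}/{self.f2}/{self.f3}"
            )
        if min(self.b1, self.b2, self.b3) <= 0:
            raise ValueError("formant bandwidths must be positive")

    @property
    def centers(self) -> tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)

    @property
    def bandwidths(self) -> tuple[float, float, float]:
        return (self.b1, self.b2, self.b3)


@dataclass(frozen=True)
class SourceSpec:
    """Inharmonic source: geometric ladder of sinusoidal components."""

    base_freq: float = 500.0
    ratio: float = 1.15
    n_components: int = 15

    def __post_init__(self) -> None:
        if self.base_freq <= 0 or self.ratio <= 1.0 or self.n_components < 1:
            raise ValueError("invalid source specification")


#: Formants of the nonfocal [ɛ]-like stimuli.
NONFOCAL_E = FormantSpec(755.0, 1646.0, 2710.0)
#: Formants of the focal [a]-like stimulus.
FOCAL_A = FormantSpec(864.0, 1287.0, 2831.0)
#: Default inharmonic source.
DEFAULT_SOURCE = SourceSpec()

#: Duration (ms) of the consonantal noise prefix in speech-analogue tokens.
FRICATIVE_MS = 150.0


@dataclass
class StimulusWaveform:
    """A mono stimulus with its synthesis metadata.

    ``samples`` are in arbitrary amplitude units until :func:`equate_rms`
    scales the set to a shared RMS target.
    """

    samples: np.ndarray
    sample_rate: float
    duration_ms: float
    category: str
    domain: str = "nonspeech"  # "nonspeech" | "speech_analogue"
    formants: FormantSpec | None = None
    ramp_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = duration_in_samples(self.duration_ms, self.sample_rate)
        if self.samples.shape != (expected,):
            raise ValueError(
                f"waveform has {self.samples.shape[0]} samples, expected "
                f"{expected} for {self.duration_ms} ms at {self.sample_rate} Hz"
            )

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def duration_in_samples(duration_ms: float, sample_rate: float) -> int:
    return int(round(duration_ms * sample_rate / 1000.0))


def component_frequencies(source: SourceSpec) -> np.ndarray:
    """Frequencies (Hz) of the geometric component ladder."""
    k = np.arange(source.n_components)
    return source.base_freq * source.ratio**k


def formant_envelope(freqs: np.ndarray, formants: FormantSpec) -> np.ndarray:
    """Magnitude of a cascade of three second-order resonators at ``freqs``.

    Each resonator is normalized to unit gain at DC, so the product keeps
    low-frequency components at their source amplitude and shapes the
    spectrum with peaks at the formant centers.
    """
    freqs = np.asarray(freqs, dtype=float)
    env = np.ones_like(freqs)
    for fc, bw in zip(formants.centers, formants.bandwidths):
        env *= fc**2 / np.abs(fc**2 - freqs**2 + 1j * freqs * bw)
    return env


def synthesize_inharmonic_complex(
    source: SourceSpec = DEFAULT_SOURCE,
    formants: FormantSpec = NONFOCAL_E,
    duration_ms: float = 220.0,
    sample_rate: float = 44100.0,
    ramp_ms: float = 5.0,
    category: str = "nonfocal_e",
    phases: np.ndarray | None = None,
) -> StimulusWaveform:
    """Sum of inharmonic sinusoids weighted by the formant envelope.

    ``phases`` (radians, one per component) default to zero; pass e.g.
    ``rng.uniform(0, 2*np.pi, source.n_components)`` for randomized phases.

    Raises ``ValueError`` if any component reaches the Nyquist frequency.
    """
    freqs = component_frequencies(source)
    nyquist = sample_rate / 2.0
    if np.any(freqs >= nyquist):
        k = int(np.argmax(freqs >= nyquist)) + 1
        raise ValueError(
            f"component {k} at {freqs[k - 1]:.1f} Hz is at or above the "
            f"Nyquist frequency {nyquist:.1f} Hz"
        )
    amps = formant_envelope(freqs, formants)
    if phases is None:
        phases = np.zeros_like(freqs)
    n = duration_in_samples(duration_ms, sample_rate)
    t = np.arange(n) / sample_rate
    sig = np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + np.asarray(phases)[:, None]),
        axis=0,
    )
    w = StimulusWaveform(
        samples=sig,
        sample_rate=sample_rate,
        duration_ms=duration_ms,
        category=category,
        domain="nonspeech",
        formants=formants,
    )
    if ramp_ms > 0:
        w = apply_linear_ramp(w, ramp_ms)
    return w


def synthesize_speech_analogue(
    formants: FormantSpec = NONFOCAL_E,
    vowel_duration_ms: float = 220.0,
    sample_rate: float = 44100.0,
    f0: float = 120.0,
    fricative_ms: float = FRICATIVE_MS,
    fricative_level: float = 0.15,
    category: str = "nonfocal_e",
    seed: int = 0,
) -> StimulusWaveform:
    """Synthetic CV-syllable stand-in: noise prefix plus a harmonic vowel.

    A 150 ms band of high-passed noise stands in for the initial fricative
    and a harmonic source (fundamental ``f0``) shaped by the same formant
    envelope stands in for the vowel.  This token is a synthetic analogue
    for simulation only; it does not reproduce a natural recorded syllable.
    """
    rng = np.random.default_rng(seed)
    nyquist = sample_rate / 2.0
    harmonics = np.arange(f0, min(4000.0, nyquist * 0.9), f0)
    amps = formant_envelope(harmonics, formants)
    n_v = duration_in_samples(vowel_duration_ms, sample_rate)
    t = np.arange(n_v) / sample_rate
    vowel = np.sum(amps[:, None] * np.sin(2 * np.pi * harmonics[:, None] * t[None, :]), axis=0)
    vowel *= _linear_ramp_envelope(n_v, duration_in_samples(5.0, sample_rate))

    n_f = duration_in_samples(fricative_ms, sample_rate)
    noise = rng.standard_normal(n_f)
    # crude high-emphasis by differencing: fricative energy sits high
    noise = np.diff(noise, prepend=0.0)
    noise *= fricative_level * np.std(vowel) / max(np.std(noise), 1e-12)
    noise *= _linear_ramp_envelope(n_f, duration_in_samples(5.0, sample_rate))

    return StimulusWaveform(
        samples=np.concatenate([noise, vowel]),
        sample_rate=sample_rate,
        duration_ms=fricative_ms + vowel_duration_ms,
        category=category,
        domain="speech_analogue",
        formants=formants,
    )


def _linear_ramp_envelope(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    if n_ramp > 0:
        up = np.arange(n_ramp) / n_ramp  # starts at exactly 0
        env[:n_ramp] = up
        env[n - n_ramp:] = up[::-1]
    return env


def apply_linear_ramp(w: StimulusWaveform, ramp_ms: float) -> StimulusWaveform:
    """Linear 0→1 onset and 1→0 offset amplitude ramps of ``ramp_ms``."""
    if ramp_ms < 0:
        raise ValueError("ramp must be non-negative")
    if 2 * ramp_ms > w.duration_ms:
        raise ValueError(
            f"ramp of {ramp_ms} ms does not fit twice into a "
            f"{w.duration_ms} ms stimulus"
        )
    if ramp_ms == 0:
        return replace(w, samples=w.samples.copy())
    n_ramp = duration_in_samples(ramp_ms, w.sample_rate)
    env = _linear_ramp_envelope(len(w.samples), n_ramp)
    return replace(w, samples=w.samples * env, ramp_ms=ramp_ms)


def equate_rms(
    waveforms: Sequence[StimulusWaveform], target_rms: float = 0.05
) -> list[StimulusWaveform]:
    """Scale each waveform to the shared RMS target (shape-preserving)."""
    if target_rms <= 0:
        raise ValueError("target RMS must be positive")
    out = []
    for w in waveforms:
        r = w.rms
        if r == 0:
            raise ValueError(f"cannot equate RMS of all-zero waveform {w.category!r}")
        out.append(replace(w, samples=w.samples * (target_rms / r)))
    return out


def estimate_formant_peaks(
    w: StimulusWaveform,
    n_peaks: int | None = None,
    lpc_order: int = 6,
    analysis_rate: float = 8000.0,
    preemphasis: float = 0.97,
) -> np.ndarray:
    """Spectral-envelope peak frequencies via all-pole (LPC) modelling.

    The waveform is resampled to ``analysis_rate``, pre-emphasized, and an
    autocorrelation-method LPC fit of ``lpc_order`` is computed; the local
    maxima of the all-pole envelope ``1/|A(e^{jw})|`` are returned in
    ascending order.  An order of 6 (one pole pair per expected formant)
    keeps the envelope from locking onto individual source components of
    the inharmonic ladder.  Used to verify that synthesis places the
    spectral-envelope maxima at the requested formant centers.
    """
    if w.duration_ms < 50:
        raise ValueError("waveform shorter than 50 ms: too short for envelope estimation")
    x = w.samples
    if w.sample_rate != analysis_rate:
        from fractions import Fraction

        frac = Fraction(analysis_rate / w.sample_rate).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    if preemphasis:
        x = np.append(x[0], x[1:] - preemphasis * x[:-1])
    x = x * np.hamming(len(x))
    a = _lpc(x, lpc_order)
    from scipy.signal import find_peaks, freqz

    freqs, h = freqz(1.0, a, worN=4096, fs=analysis_rate)
    env = np.abs(h)
    idx, _ = find_peaks(env)
    peaks = np.sort(freqs[idx])
    peaks = peaks[peaks > 50.0]
    if n_peaks is not None:
        peaks = peaks[:n_peaks]
    return peaks


def _lpc(x: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method linear-prediction coefficients [1, a1..ap]."""
    x = np.asarray(x, dtype=float)
    r = np.correlate(x, x, mode="full")[len(x) - 1 : len(x) + order]
    r[0] *= 1.0 + 1e-9  # tiny ridge for numerical safety
    a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate([[1.0], a])


#: (category, formants, vowel duration ms) of the four stimulus types.
STIMULUS_TABLE: dict[str, tuple[FormantSpec, float]] = {
    "focal_a": (FOCAL_A, 220.0),
    "nonfocal_e": (NONFOCAL_E, 220.0),
    "short_e": (NONFOCAL_E, 180.0),
    "long_e": (NONFOCAL_E, 360.0),
}


def stimulus_duration_ms(category: str, domain: str) -> float:
    """Total stimulus duration: vowel/tone duration, plus the consonantal
    prefix for speech-analogue tokens."""
    _, dur = STIMULUS_TABLE[category]
    return dur + (FRICATIVE_MS if domain.startswith("speech") else 0.0)


def standard_stimulus_set(
    domain: str = "nonspeech",
    sample_rate: float = 44100.0,
    target_rms: float = 0.05,
    seed: int = 0,
) -> dict[str, StimulusWaveform]:
    """The four stimulus types of one domain, RMS-equated."""
    ws = []
    for cat, (formants, dur) in STIMULUS_TABLE.items():
        if domain == "nonspeech":
            ws.append(
                synthesize_inharmonic_complex(
                    formants=formants, duration_ms=dur, sample_rate=sample_rate,
                    category=cat,
                )
            )
        elif domain in ("speech", "speech_analogue"):
            ws.append(
                synthesize_speech_analogue(
                    formants=formants, vowel_duration_ms=dur,
                    sample_rate=sample_rate, category=cat, seed=seed,
                )
            )
        else:
            raise ValueError(f"unknown domain {domain!r}")
    ws = equate_rms(ws, target_rms)
    return {w.category: w for w in ws}


def write_wav(w: StimulusWaveform, path: str | Path) -> Path:
    """Write a stimulus as 16-bit PCM WAV; clips above full scale."""
    path = Path(path)
    data = w.samples
    peak = np.max(np.abs(data))
    if peak > 1.0:
        data = data * (0.99 / peak)
    wavfile.write(path, int(w.sample_rate), (np.clip(data, -1, 1) * 32767).astype(np.int16))
    return path
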