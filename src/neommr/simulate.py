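"""Forward model: synthetic multichannel EEG for virtual newborns.

Each stimulus token evokes a smooth kernel made of a Gaussian *onset*
component peaking ~300 ms after vowel/tone onset and a Gaussian *offset*
component peaking ~350 ms after stimulus offset.  Deviant-role tokens
additionally receive mismatch-response deflections: half-sine bumps placed
in the early (80-220 ms) and late (500-700 ms) post-change-onset windows.
On top of the evoked part the generator adds spatially correlated 1/f
background noise band-limited to the amplifier bandwidth (0.3-100 Hz) and
occasional high-amplitude artifact pulses that the ±90 µV rejection stage
is meant to catch.

Amplitude convention: every amplitude parameter is the *mean amplitude over
its scoring window* in µV, so the injected area under the curve of a
component over its window is exactly ``amplitude x window width`` µV·ms —
an analytic ground truth for the downstream measures.

Default effect sizes are anchored to the scale of newborn vowel/tone ERP
studies: sensory responses of a few tens to hundreds of µV·ms, speech
responses larger than nonspeech, a spectral ([ɛ] vs [a]) onset effect at
central channels, a durational offset effect at the midline, and a
left-lateralized negative-going asymmetry between from-E and to-E deviants
that exists for speech only.  What the generator does and does not emulate
about real infant EEG is laid out in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .measures import (
    EARLY_MMR_WINDOW,
    LATE_MMR_WINDOW,
    change_onset_ms,
    deviant_direction_label,
    vowel_onset_offset_ms,
    DEFAULT_REGIONS,
)
from .paradigm import BlockConfig, EventSequence, ROLE_DEVIANT, generate_block
from .stimuli import STIMULUS_TABLE

__all__ = [
    "CHANNELS",
    "ErpTemplateParams",
    "MmrEffectParams",
    "NoiseParams",
    "RawRecording",
    "make_erp_kernel",
    "simulate_subject",
    "simulate_cohort",
    "block_config_for",
]

#: The 6-channel montage (nose reference by convention; metadata only).
CHANNELS = ("F3", "FZ", "F4", "C3", "CZ", "C4")

#: Scoring-window widths used to convert window-mean µV to Gaussian peaks.
ONSET_WIN_WIDTH_MS = 200.0
OFFSET_WIN_WIDTH_MS = 200.0

#: Duration contrast codes (used for the midline offset-duration effect).
DURATION_CODE = {360.0: 1.0, 220.0: -0.2, 180.0: -0.6}


@dataclass(frozen=True)
class ErpTemplateParams:
    """Shape and topography of the sensory ERP kernel.

    All amplitudes are window-mean µV (see module docstring); latencies are
    ms.  ``spectrum_effect_central`` is the [ɛ]-minus-[a] onset-response
    difference at central channels; ``duration_effect_midline`` is the
    offset-response change per unit duration code at midline channels.
    Both effects apply to the speech domain only (as configured), mirroring
    the domain-specific acoustic tuning they stand in for.
    """

    onset_peak_ms: float = 300.0  # after vowel/tone onset
    offset_peak_ms: float = 350.0  # after stimulus offset
    component_width_ms: float = 60.0  # Gaussian SD
    onset_amp_uv: float = 0.45
    offset_amp_uv: float = 0.25
    domain_gain: float = 1.7  # speech multiplier
    spectrum_effect_central_uv: float = 0.27
    duration_effect_midline_uv: float = 0.29
    effects_in_nonspeech: bool = False
    subject_gain_sd: float = 0.2  # SD of per-subject amplitude multiplier

    def __post_init__(self) -> None:
        if self.component_width_ms <= 0:
            raise ValueError("component width must be positive")


@dataclass(frozen=True)
class MmrEffectParams:
    """Mismatch-response deflections added to deviant-role epochs.

    ``base_*`` is the deflection shared by all deviants (the immature,
    positive-going newborn MMR); ``asymmetry_*`` is the signed from-E minus
    to-E difference, applied with per-region weights (left strongest,
    absent on the right) and, by default, in the speech domain only.
    ``subject_sd_uv`` is the SD of a per-infant additive offset on the
    deflection amplitude, shared by both deviant directions — the
    between-infant variability in overall mismatch responsiveness.
    """

    base_early_uv: float = 0.19
    base_late_uv: float = 0.04
    asymmetry_early_uv: float = -0.64
    asymmetry_late_uv: float = -0.88
    asymmetry_region_weights: tuple[tuple[str, float], ...] = (
        ("left", 1.0),
        ("midline", 0.6),
        ("right", 0.0),
    )
    speech_only: bool = True
    subject_sd_uv: float = 0.45

    def region_weight(self, region: str) -> float:
        return dict(self.asymmetry_region_weights).get(region, 0.0)

    def deflection_uv(
        self, window: str, domain: str, dimension: str, direction: str,
        region: str, subject_offset_uv: float = 0.0,
    ) -> float:
        """Window-mean deflection for one deviant cell."""
        base = self.base_early_uv if window == "early" else self.base_late_uv
        asym = self.asymmetry_early_uv if window == "early" else self.asymmetry_late_uv
        if self.speech_only and not domain.startswith("speech"):
            asym = 0.0
        sign = 0.5 if direction == "from_E" else -0.5
        return base + subject_offset_uv + sign * asym * self.region_weight(region)


@dataclass(frozen=True)
class NoiseParams:
    """Background-noise and artifact model."""

    spectral_exponent: float = 1.0  # power ∝ 1/f^exponent
    rms_uv: float = 15.0  # background level; artifacts, not noise, drive ±90 µV rejections
    channel_correlation: float = 0.5
    artifact_rate: float = 0.25  # per stimulus token
    artifact_amp_uv: float = 200.0
    artifact_width_ms: float = 50.0
    band_hz: tuple[float, float] = (0.3, 100.0)

    def __post_init__(self) -> None:
        if self.rms_uv < 0 or not (0 <= self.channel_correlation <= 1):
            raise ValueError("invalid noise parameters")
        if not (0 <= self.artifact_rate <= 1):
            raise ValueError("artifact rate must be a probability")


@dataclass
class RawRecording:
    """Continuous multichannel EEG (µV) with its event table."""

    signal: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    channels: tuple[str, ...]
    events: EventSequence
    subject_id: str = "S000"
    domain: str = "nonspeech"
    dimension: str = "spectral"

    def __post_init__(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError("signal must be (n_channels, n_samples)")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sample_rate


def block_config_for(dimension: str, seed: int = 0, **kwargs) -> BlockConfig:
    """Default roving-standard block for one stimulus dimension."""
    if dimension == "spectral":
        return BlockConfig(type_a="nonfocal_e", type_b="focal_a", seed=seed, **kwargs)
    if dimension == "durational":
        return BlockConfig(type_a="short_e", type_b="long_e", seed=seed, **kwargs)
    raise ValueError(f"unknown dimension {dimension!r}")


def _gaussian_windowed_mean_to_peak(width_ms: float, window_width_ms: float) -> float:
    """Factor converting a window-mean amplitude to a Gaussian peak.

    For a Gaussian of SD ``width_ms`` centred in a window of
    ``window_width_ms``, mean-over-window = peak * g where
    g = SD*sqrt(2*pi)*(Phi(h)-Phi(-h))/window_width, h = half-window/SD.
    """
    from scipy.stats import norm

    h = (window_width_ms / 2) / width_ms
    g = width_ms * np.sqrt(2 * np.pi) * (norm.cdf(h) - norm.cdf(-h)) / window_width_ms
    return 1.0 / g


def _half_sine(t_ms: np.ndarray, start_ms: float, stop_ms: float, mean_amp_uv: float) -> np.ndarray:
    """Half-sine bump whose mean over [start, stop] is ``mean_amp_uv``.

    A half-sine of peak P has mean 2P/pi over its support, so P = mean*pi/2.
    """
    out = np.zeros_like(t_ms)
    m = (t_ms >= start_ms) & (t_ms <= stop_ms)
    out[m] = (mean_amp_uv * np.pi / 2) * np.sin(
        np.pi * (t_ms[m] - start_ms) / (stop_ms - start_ms)
    )
    return out


def make_erp_kernel(
    params: ErpTemplateParams,
    category: str,
    domain: str,
    channel: str,
    sample_rate: float,
    support_ms: float = 1100.0,
    regions=DEFAULT_REGIONS,
) -> np.ndarray:
    """Sensory kernel for one stimulus category at one channel.

    The returned array covers ``[0, support_ms)`` after *token* onset.  The
    onset Gaussian peaks ``onset_peak_ms`` after vowel/tone onset (150 ms
    into a speech token) and the offset Gaussian ``offset_peak_ms`` after
    stimulus offset, so a duration difference shifts the offset component
    by exactly that difference.
    """
    if category not in STIMULUS_TABLE:
        raise ValueError(f"unknown stimulus category {category!r}")
    _, dur = STIMULUS_TABLE[category]
    v0 = vowel_onset_offset_ms(domain)
    t_onset_peak = v0 + params.onset_peak_ms
    t_offset_peak = v0 + dur + params.offset_peak_ms
    if not (0 < t_onset_peak < support_ms and 0 < t_offset_peak < support_ms):
        raise ValueError("component latency falls outside the kernel support")

    speechlike = domain.startswith("speech")
    gain = params.domain_gain if speechlike else 1.0
    apply_fx = speechlike or params.effects_in_nonspeech

    onset_mean = params.onset_amp_uv * gain
    offset_mean = params.offset_amp_uv * gain
    if apply_fx and regions.anteriority_of(channel) == "central":
        # [ɛ]-family categories sit +effect/2 above the grand mean, [a] -effect/2
        half = params.spectrum_effect_central_uv / 2
        onset_mean += half if category != "focal_a" else -half
    if apply_fx and regions.laterality_of(channel) == "midline":
        offset_mean += params.duration_effect_midline_uv * DURATION_CODE[dur]

    k_on = _gaussian_windowed_mean_to_peak(params.component_width_ms, ONSET_WIN_WIDTH_MS)
    k_off = _gaussian_windowed_mean_to_peak(params.component_width_ms, OFFSET_WIN_WIDTH_MS)

    n = int(round(support_ms * sample_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sample_rate
    w = params.component_width_ms
    kernel = onset_mean * k_on * np.exp(-0.5 * ((t - t_onset_peak) / w) ** 2)
    kernel += offset_mean * k_off * np.exp(-0.5 * ((t - t_offset_peak) / w) ** 2)
    return kernel


def _mmr_kernel(
    mmr: MmrEffectParams,
    category: str,
    domain: str,
    dimension: str,
    channel: str,
    sample_rate: float,
    support_ms: float,
    subject_offset_uv: float,
    regions=DEFAULT_REGIONS,
) -> np.ndarray:
    """Deflection added to a deviant token of ``category`` at one channel."""
    direction = deviant_direction_label(dimension, category)
    region = regions.laterality_of(channel)
    c0 = change_onset_ms(dimension, domain)
    n = int(round(support_ms * sample_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sample_rate
    out = np.zeros(n)
    for name, (w0, w1) in (("early", EARLY_MMR_WINDOW), ("late", LATE_MMR_WINDOW)):
        amp = mmr.deflection_uv(name, domain, dimension, direction, region, subject_offset_uv)
        out += _half_sine(t, c0 + w0, c0 + w1, amp)
    return out


def _one_over_f_noise(
    n_samples: int, n_channels: int, fs: float, p: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Correlated 1/f noise, band-limited to the amplifier bandwidth."""
    if p.rms_uv == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    f_lo = max(p.band_hz[0], fs / n_samples)
    pos = freqs > 0
    shape[pos] = np.maximum(freqs[pos], f_lo) ** (-p.spectral_exponent / 2.0)

    def shaped(n_streams: int) -> np.ndarray:
        white = rng.standard_normal((n_streams, n_samples))
        spec = np.fft.rfft(white, axis=1) * shape
        return np.fft.irfft(spec, n=n_samples, axis=1)

    common = shaped(1)
    own = shaped(n_channels)
    c = p.channel_correlation
    x = np.sqrt(c) * common + np.sqrt(1 - c) * own

    # amplifier band emulation (zero-phase, applied to the noise only)
    nyq = fs / 2
    hi = min(p.band_hz[1], 0.95 * nyq)
    sos = butter(4, [p.band_hz[0] / nyq, hi / nyq], btype="band", output="sos")
    x = sosfiltfilt(sos, x, axis=1)

    x *= p.rms_uv / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def _add_artifacts(
    signal: np.ndarray,
    events: EventSequence,
    fs: float,
    p: NoiseParams,
    rng: np.random.Generator,
) -> int:
    """Inject high-amplitude pulses on a Bernoulli subset of tokens.

    Pulses are confined to 50-850 ms after token onset so each one
    contaminates exactly one epoch even though consecutive epochs overlap.
    Returns the number of affected tokens.
    """
    n_hit = 0
    n_width = max(1, int(round(p.artifact_width_ms * fs / 1000.0)))
    pulse = np.hanning(n_width) * p.artifact_amp_uv * 1.5
    for e in events:
        if rng.random() >= p.artifact_rate:
            continue
        n_hit += 1
        ch = rng.integers(0, signal.shape[0])
        t_ms = rng.uniform(50.0, 850.0 - p.artifact_width_ms)
        i0 = int(round((e.onset_s + t_ms / 1000.0) * fs))
        if i0 + n_width > signal.shape[1]:
            continue
        signal[ch, i0 : i0 + n_width] += pulse * rng.choice([-1.0, 1.0])
    return n_hit


def simulate_subject(
    events: EventSequence,
    erp: ErpTemplateParams = ErpTemplateParams(),
    mmr: MmrEffectParams = MmrEffectParams(),
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    domain: str = "nonspeech",
    dimension: str = "spectral",
    sample_rate: float = 3000.0,
    subject_id: str = "S000",
    subject_gain: float | None = None,
    subject_mmr_offset_uv: float | None = None,
) -> RawRecording:
    """Simulate one continuous recording of one presentation block.

    Deterministic given ``seed``.  ``subject_gain`` (multiplier on sensory
    kernel amplitudes) and ``subject_mmr_offset_uv`` (additive offset on
    the MMR deflection) default to draws from the subject-effect
    distributions; a cohort driver passes the same values for both blocks
    of one infant.
    """
    rng = np.random.default_rng(seed)
    if subject_gain is None:
        subject_gain = max(0.1, 1.0 + erp.subject_gain_sd * rng.standard_normal())
    if subject_mmr_offset_uv is None:
        subject_mmr_offset_uv = mmr.subject_sd_uv * rng.standard_normal()

    soa_ms = events.config.soa_s * 1000.0
    lock_ms = vowel_onset_offset_ms(domain)
    # kernel support stops where the *next* epoch's baseline begins
    support_ms = soa_ms - 100.0 + lock_ms

    last_onset = max(e.onset_s for e in events)
    n_samples = int(round((last_onset + support_ms / 1000.0 + 0.1) * sample_rate))
    signal = np.zeros((len(CHANNELS), n_samples))

    categories = sorted({e.category for e in events})
    sens = {
        (cat, ch): subject_gain
        * make_erp_kernel(erp, cat, domain, ch, sample_rate, support_ms)
        for cat in categories
        for ch in CHANNELS
    }
    dev = {
        (cat, ch): _mmr_kernel(
            mmr, cat, domain, dimension, ch, sample_rate, support_ms, subject_mmr_offset_uv
        )
        for cat in categories
        for ch in CHANNELS
    }

    for e in events:
        i0 = int(round(e.onset_s * sample_rate))
        for ci, ch in enumerate(CHANNELS):
            k = sens[(e.category, ch)]
            if e.role == ROLE_DEVIANT:
                k = k + dev[(e.category, ch)]
            i1 = min(i0 + len(k), n_samples)
            signal[ci, i0:i1] += k[: i1 - i0]

    signal += _one_over_f_noise(n_samples, len(CHANNELS), sample_rate, noise, rng)
    if noise.artifact_rate > 0 and noise.artifact_amp_uv > 0:
        _add_artifacts(signal, events, sample_rate, noise, rng)

    return RawRecording(
        signal=signal,
        sample_rate=sample_rate,
        channels=CHANNELS,
        events=events,
        subject_id=subject_id,
        domain=domain,
        dimension=dimension,
    )


def simulate_cohort(
    n_subjects: int,
    domain: str = "speech",
    dimensions: Sequence[str] = ("spectral", "durational"),
    erp: ErpTemplateParams = ErpTemplateParams(),
    mmr: MmrEffectParams = MmrEffectParams(),
    noise: NoiseParams = NoiseParams(),
    master_seed: int = 0,
    sample_rate: float = 3000.0,
    block_kwargs: dict | None = None,
) -> list[RawRecording]:
    """Simulate a cohort: one recording per subject and dimension.

    Per-subject seeds derive reproducibly from ``master_seed``; each
    infant's random amplitude gain and mismatch-responsiveness offset are
    shared across their blocks.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    ss = np.random.SeedSequence(master_seed)
    out: list[RawRecording] = []
    block_kwargs = dict(block_kwargs or {})
    for si, child in enumerate(ss.spawn(n_subjects)):
        sub_rng = np.random.default_rng(child)
        gain = max(0.1, 1.0 + erp.subject_gain_sd * sub_rng.standard_normal())
        u_mmr = mmr.subject_sd_uv * sub_rng.standard_normal()
        block_seeds = sub_rng.integers(0, 2**31 - 1, size=2 * len(dimensions))
        for di, dim in enumerate(dimensions):
            cfg = block_config_for(dim, seed=int(block_seeds[2 * di]), **block_kwargs)
            events = generate_block(cfg)
            out.append(
                simulate_subject(
                    events,
                    erp=erp,
                    mmr=mmr,
                    noise=noise,
                    seed=int(block_seeds[2 * di + 1]),
                    domain=domain,
                    dimension=dim,
                    sample_rate=sample_rate,
                    subject_id=f"S{si:03d}",
                    subject_gain=gain,
                    subject_mmr_offset_uv=u_mmr,
                )
            )
    return out
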