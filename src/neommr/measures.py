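"""Latency windows, signed AUC, difference waves, and channel pooling.

Sensory ERPs are scored in an onset window 200-400 ms after vowel/tone onset
and an offset window 250-450 ms after vowel/tone offset.  Mismatch responses
are scored on deviant-minus-standard difference waves in an early window
80-220 ms and a late window 500-700 ms after *change onset*: stimulus onset
for spectral deviations, short-stimulus offset (+180 ms) for durational
deviations.  All quantities are signed areas under the curve in µV·ms.

For speech-analogue tokens the vowel begins 150 ms after token onset (the
consonantal prefix), so every vowel-anchored window shifts by 150 ms on the
epoch time base; epochs are time-locked to token onset throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import FRICATIVE_MS, STIMULUS_TABLE

__all__ = [
    "Window",
    "AnalysisWindows",
    "RegionMap",
    "DEFAULT_REGIONS",
    "ONSET_WINDOW",
    "OFFSET_WINDOW",
    "EARLY_MMR_WINDOW",
    "LATE_MMR_WINDOW",
    "DURATIONAL_CHANGE_OFFSET_MS",
    "resolve_windows",
    "change_onset_ms",
    "auc",
    "difference_wave",
    "pool_channels",
    "pool_regions",
    "deviant_direction_label",
]

#: Vowel/tone-onset-relative sensory windows (ms).
ONSET_WINDOW = (200.0, 400.0)
#: Stimulus-offset-relative sensory window (ms).
OFFSET_WINDOW = (250.0, 450.0)
#: Change-onset-relative MMR windows (ms).
EARLY_MMR_WINDOW = (80.0, 220.0)
LATE_MMR_WINDOW = (500.0, 700.0)
#: Durational change onset: the short stimulus' offset, 180 ms after vowel onset.
DURATIONAL_CHANGE_OFFSET_MS = 180.0


@dataclass(frozen=True)
class Window:
    """A closed latency interval on the epoch time base (ms after token onset)."""

    start_ms: float
    stop_ms: float

    def __post_init__(self) -> None:
        if not self.stop_ms > self.start_ms:
            raise ValueError(f"empty window [{self.start_ms}, {self.stop_ms}]")

    @property
    def width_ms(self) -> float:
        return self.stop_ms - self.start_ms

    def shifted(self, offset_ms: float) -> "Window":
        return Window(self.start_ms + offset_ms, self.stop_ms + offset_ms)


@dataclass(frozen=True)
class AnalysisWindows:
    """Absolute (token-onset-relative) analysis windows for one stimulus."""

    onset: Window
    offset: Window
    early_mmr: Window
    late_mmr: Window
    vowel_onset_ms: float
    stimulus_duration_ms: float
    change_onset_ms: float

    def on_epoch(self) -> dict[str, Window]:
        """Windows on the epoch time base (epochs are vowel/tone-locked),
        i.e. shifted by minus the vowel onset."""
        return {
            name: getattr(self, name).shifted(-self.vowel_onset_ms)
            for name in ("onset", "offset", "early_mmr", "late_mmr")
        }


def vowel_onset_offset_ms(domain: str) -> float:
    """Vowel/tone onset relative to token onset: 150 ms for speech-analogue
    tokens (consonantal prefix), 0 for nonspeech."""
    return FRICATIVE_MS if domain.startswith("speech") else 0.0


def change_onset_ms(dimension: str, domain: str) -> float:
    """Change onset on the epoch time base.

    Spectral deviations differ from the first vowel/tone sample, so change
    onset equals vowel/tone onset; durational deviations only become
    detectable at the short stimulus' offset, 180 ms later.
    """
    base = vowel_onset_offset_ms(domain)
    if dimension == "spectral":
        return base
    if dimension == "durational":
        return base + DURATIONAL_CHANGE_OFFSET_MS
    raise ValueError(f"unknown dimension {dimension!r}")


def resolve_windows(category: str, domain: str, dimension: str) -> AnalysisWindows:
    """Absolute analysis windows for one stimulus category and domain.

    For the three vowel/tone durations the offset window works out (in
    vowel-onset-relative terms) to 470-670 ms (220 ms stimuli), 430-630 ms
    (180 ms) and 610-810 ms (360 ms).
    """
    if category not in STIMULUS_TABLE:
        raise ValueError(f"unknown stimulus category {category!r}")
    _, dur = STIMULUS_TABLE[category]
    v0 = vowel_onset_offset_ms(domain)
    c0 = change_onset_ms(dimension, domain)
    return AnalysisWindows(
        onset=Window(*ONSET_WINDOW).shifted(v0),
        offset=Window(*OFFSET_WINDOW).shifted(v0 + dur),
        early_mmr=Window(*EARLY_MMR_WINDOW).shifted(c0),
        late_mmr=Window(*LATE_MMR_WINDOW).shifted(c0),
        vowel_onset_ms=v0,
        stimulus_duration_ms=dur,
        change_onset_ms=c0,
    )


def auc(
    waveform: np.ndarray,
    window: Window,
    sample_rate: float,
    t0_ms: float = -100.0,
) -> float:
    """Signed trapezoidal integral (µV·ms) of ``waveform`` over ``window``.

    ``t0_ms`` is the time of the first sample.  Window edges are snapped to
    the sampling grid (nearest sample, at most half a sample of shift); the
    snapped endpoints are both included in the quadrature.
    """
    waveform = np.asarray(waveform, dtype=float)
    dt_ms = 1000.0 / sample_rate
    i0 = int(round((window.start_ms - t0_ms) / dt_ms))
    i1 = int(round((window.stop_ms - t0_ms) / dt_ms))
    if i0 < 0 or i1 >= waveform.shape[-1]:
        raise ValueError(
            f"window [{window.start_ms}, {window.stop_ms}] ms exceeds waveform "
            f"support [{t0_ms}, {t0_ms + (waveform.shape[-1] - 1) * dt_ms}] ms"
        )
    return float(np.trapezoid(waveform[..., i0 : i1 + 1], dx=dt_ms, axis=-1))


def difference_wave(deviant: "EvokedResponse", standard: "EvokedResponse"):
    """Deviant-minus-standard waveform for one physical stimulus.

    Both inputs must be ERPs of the *same physical stimulus* (and subject):
    the mismatch response is defined by the role contrast, not a stimulus
    contrast, so mismatched identities raise.
    Returns a new :class:`~neommr.preprocess.EvokedResponse`.
    """
    for key in ("category", "subject", "domain"):
        a, b = deviant.coords.get(key), standard.coords.get(key)
        if a != b:
            raise ValueError(
                f"difference wave requires matching {key}: {a!r} vs {b!r}"
            )
    from .preprocess import EvokedResponse

    coords = dict(deviant.coords)
    coords["role"] = "difference"
    return EvokedResponse(
        data=deviant.data - standard.data,
        sample_rate=deviant.sample_rate,
        t0_ms=deviant.t0_ms,
        channels=deviant.channels,
        n_epochs=min(deviant.n_epochs, standard.n_epochs),
        snr=float("nan"),
        coords=coords,
    )


@dataclass(frozen=True)
class RegionMap:
    """Grouping of the 6-channel montage into scalp regions."""

    left: tuple[str, str] = ("F3", "C3")
    midline: tuple[str, str] = ("FZ", "CZ")
    right: tuple[str, str] = ("F4", "C4")
    frontal: tuple[str, str, str] = ("F3", "FZ", "F4")
    central: tuple[str, str, str] = ("C3", "CZ", "C4")

    @property
    def laterality(self) -> dict[str, tuple[str, ...]]:
        return {"left": self.left, "midline": self.midline, "right": self.right}

    @property
    def anteriority(self) -> dict[str, tuple[str, ...]]:
        return {"frontal": self.frontal, "central": self.central}

    def laterality_of(self, channel: str) -> str:
        for name, chs in self.laterality.items():
            if channel in chs:
                return name
        raise ValueError(f"channel {channel!r} not in montage")

    def anteriority_of(self, channel: str) -> str:
        for name, chs in self.anteriority.items():
            if channel in chs:
                return name
        raise ValueError(f"channel {channel!r} not in montage")


DEFAULT_REGIONS = RegionMap()


def pool_channels(
    data: np.ndarray, channels: list[str], pool: tuple[str, ...]
) -> np.ndarray:
    """Mean waveform over the channels of one region."""
    missing = [c for c in pool if c not in channels]
    if missing:
        raise ValueError(f"missing channels for pooling: {missing}")
    idx = [channels.index(c) for c in pool]
    return np.mean(np.asarray(data)[idx], axis=0)


def pool_regions(
    auc_records: pd.DataFrame, regions: RegionMap = DEFAULT_REGIONS
) -> pd.DataFrame:
    """Average per-channel AUC records into laterality regions.

    By linearity of the integral this equals pooling waveforms first and
    integrating after.  Input needs a ``channel`` and a ``value`` column;
    all other columns are treated as coordinates.
    """
    df = auc_records.copy()
    df["region"] = df["channel"].map(regions.laterality_of)
    keys = [c for c in df.columns if c not in ("channel", "value")]
    out = df.groupby(keys, as_index=False, observed=True)["value"].mean()
    return out


def deviant_direction_label(dimension: str, deviant_category: str) -> str:
    """Direction coding of a deviant: 'to_E' or 'from_E'.

    Spectral: the [ɛ]-like deviant (appearing after [a] standards) is a
    change *to* E, the [a]-like deviant a change *from* E.  Durational: the
    short deviant is 'to_E', the long deviant 'from_E'.
    """
    table = {
        ("spectral", "nonfocal_e"): "to_E",
        ("spectral", "focal_a"): "from_E",
        ("durational", "short_e"): "to_E",
        ("durational", "long_e"): "from_E",
    }
    try:
        return table[(dimension, deviant_category)]
    except KeyError:
        raise ValueError(
            f"no deviant direction for dimension={dimension!r}, "
            f"category={deviant_category!r}"
        ) from None
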