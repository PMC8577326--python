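"""Recording and configuration I/O.

Recordings travel as EDF (16-bit integers with per-channel physical
scaling in µV) plus two plain-text sidecars: ``<stem>.events.csv`` with the
token-level event table (which round-trips exactly) and
``<stem>.meta.json`` with subject/block metadata.  Event roles live in the
CSV sidecar rather than EDF annotations because annotation dialects vary
across EDF writers.

The EDF writer here is a minimal single-purpose implementation of the
16-bit EDF layout; reading goes through :mod:`mne`, which keeps writer and
parser independent of each other.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .paradigm import BlockConfig, EventSequence
from .simulate import (
    CHANNELS,
    ErpTemplateParams,
    MmrEffectParams,
    NoiseParams,
    RawRecording,
)

logger = logging.getLogger(__name__)

__all__ = [
    "write_recording",
    "read_recording",
    "write_edf",
    "PipelineConfig",
    "load_config",
    "save_config",
]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    signal_uv: np.ndarray,
    sample_rate: float,
    channels: list[str] | tuple[str, ...],
    path: str | Path,
    patient_id: str = "X",
    recording_id: str = "neommr simulation",
) -> Path:
    """Write a (n_channels, n_samples) µV array as 16-bit EDF.

    One-second data records; the last record is zero-padded.  Physical
    min/max are set per channel to the symmetric data range, so the
    quantization step is ``2*max|x| / 65535`` µV.
    """
    path = Path(path)
    signal_uv = np.asarray(signal_uv, dtype=float)
    n_ch, n_samp = signal_uv.shape
    spr = int(round(sample_rate))  # samples per 1 s record
    if abs(spr - sample_rate) > 1e-9:
        raise ValueError("EDF writer needs an integer sample rate")
    n_rec = int(np.ceil(n_samp / spr))

    phys_max = np.maximum(np.abs(signal_uv).max(axis=1), 1e-6)
    dig_max, dig_min = 32767, -32768

    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad(recording_id, 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        [_pad(ch, 16) for ch in channels],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{-m:.6g}"[:8], 8) for m in phys_max],
        [_pad(f"{m:.6g}"[:8], 8) for m in phys_max],
        [_pad(str(dig_min), 8)] * n_ch,
        [_pad(str(dig_max), 8)] * n_ch,
        [_pad("HP:0.3Hz LP:100Hz", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    sig_header = b"".join(b"".join(f) for f in fields)

    # EDF affine map: phys = (dig - dig_min) * (pmax - pmin)/(dmax - dmin) + pmin
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = signal_uv
    gain = (2 * phys_max)[:, None] / (dig_max - dig_min)
    digital = np.clip(
        np.round((padded + phys_max[:, None]) / gain) + dig_min, dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as EDF plus its event-table and metadata sidecars."""
    path = Path(path)
    write_edf(
        rec.signal, rec.sample_rate, list(rec.channels), path,
        patient_id=rec.subject_id,
        recording_id=f"neommr {rec.domain}/{rec.dimension}",
    )
    rec.events.to_csv(path.with_suffix(".events.csv"))
    meta = {
        "subject_id": rec.subject_id,
        "domain": rec.domain,
        "dimension": rec.dimension,
        "sample_rate": rec.sample_rate,
        "channels": list(rec.channels),
        "block_config": dataclasses.asdict(rec.events.config),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: str | Path) -> RawRecording:
    """Read an EDF recording and its sidecars back into a RawRecording.

    Parsing goes through mne; only channels of the expected 6-channel
    montage are loaded (extras are logged and ignored), and a montage with
    none of the expected names raises.  A missing event sidecar raises.
    """
    import mne

    path = Path(path)
    ev_path = path.with_suffix(".events.csv")
    meta_path = path.with_suffix(".meta.json")
    if not ev_path.exists():
        raise FileNotFoundError(f"missing event sidecar {ev_path}")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    upper = {ch.upper(): ch for ch in raw.ch_names}
    present = [c for c in CHANNELS if c in upper]
    if not present:
        raise ValueError(
            f"no expected channels {CHANNELS} in EDF montage {raw.ch_names}; "
            "an explicit mapping is required"
        )
    extra = [c for c in raw.ch_names if c.upper() not in CHANNELS]
    if extra:
        logger.info("read_recording: ignoring unexpected channels %s", extra)
    data = raw.get_data(picks=[upper[c] for c in present]) * 1e6  # V -> µV

    cfg_dict = meta.get("block_config", {})
    cfg_dict["train_lengths"] = tuple(cfg_dict.get("train_lengths", (4, 5, 6, 7, 8)))
    cfg = BlockConfig(**cfg_dict)
    events = EventSequence.from_dataframe(pd.read_csv(ev_path), cfg)
    return RawRecording(
        signal=data,
        sample_rate=float(raw.info["sfreq"]),
        channels=tuple(present),
        events=events,
        subject_id=meta.get("subject_id", "S000"),
        domain=meta.get("domain", "nonspeech"),
        dimension=meta.get("dimension", "spectral"),
    )


@dataclass
class PipelineConfig:
    """Fully serializable end-to-end run description.

    A config plus its seeds reproduces a run bit-identically through the
    deterministic stages.
    """

    n_subjects_per_domain: int = 2
    domains: tuple[str, ...] = ("speech", "nonspeech")
    dimensions: tuple[str, ...] = ("spectral", "durational")
    sample_rate: float = 3000.0
    master_seed: int = 0
    occurrences_per_length: int = 20
    reject_uv: float = 90.0
    snr_gate: float = 1.0
    erp: ErpTemplateParams = field(default_factory=ErpTemplateParams)
    mmr: MmrEffectParams = field(default_factory=MmrEffectParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    outdir: str = "neommr_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("erp", ErpTemplateParams), ("mmr", MmrEffectParams), ("noise", NoiseParams)):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                if key == "mmr" and "asymmetry_region_weights" in sub:
                    sub["asymmetry_region_weights"] = tuple(
                        (str(r), float(w)) for r, w in sub["asymmetry_region_weights"]
                    )
                if key == "noise" and "band_hz" in sub:
                    sub["band_hz"] = tuple(sub["band_hz"])
                d[key] = typ(**sub)
        for key in ("domains", "dimensions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
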