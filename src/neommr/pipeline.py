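"""End-to-end orchestration: simulate/load → preprocess → measures → stats.

`run_pipeline` ties the stages together for a whole simulated cohort and
writes the QC report, the AUC tables, the model coefficient tables and the
cell-mean tables with their CI marks.  Conservation counts (events →
epochs → kept epochs → ERPs → AUC rows) are logged at every hand-off and
collected in the QC report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from . import measures, preprocess, stats
from .io import PipelineConfig
from .measures import DEFAULT_REGIONS, deviant_direction_label, resolve_windows
from .paradigm import ROLE_DEVIANT, ROLE_STANDARD
from .preprocess import EpochSet, EvokedResponse
from .simulate import RawRecording, simulate_cohort
from .stimuli import STIMULUS_TABLE

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_recording",
    "sensory_erps",
    "sensory_auc_records",
    "mmr_auc_records",
    "run_pipeline",
]


def preprocess_recording(raw: RawRecording, reject_uv: float = 90.0) -> EpochSet:
    """Filter, downsample, epoch (vowel/tone-locked) and amplitude-reject."""
    filtered = preprocess.lowpass_40(raw)
    ds = preprocess.downsample_to_300(filtered)
    lock_s = measures.vowel_onset_offset_ms(raw.domain) / 1000.0
    es = preprocess.epoch(ds, lock_offset_s=lock_s)
    return preprocess.reject_amplitude(es, reject_uv)


def sensory_erps(es: EpochSet, raw: RawRecording) -> dict[str, EvokedResponse]:
    """Per-category sensory ERPs (non-train-initial tokens), with plus/minus
    SNR, Savitzky-Golay smoothed."""
    out: dict[str, EvokedResponse] = {}
    for cat in sorted(es.meta["category"].unique()):
        mask = (es.meta["category"] == cat) & es.meta["sensory"]
        sub = es.select(mask.to_numpy())
        coords = {
            "subject": raw.subject_id, "domain": raw.domain,
            "dimension": raw.dimension, "category": cat, "role": "sensory",
        }
        er = preprocess.average(sub, coords)
        if er.n_epochs >= 2:
            er.snr = preprocess.plusminus_snr(sub)
        if er.n_epochs >= 1:
            er = preprocess.savgol_smooth(er)
        out[cat] = er
    return out


def sensory_auc_records(
    erps: dict[str, EvokedResponse], raw: RawRecording, snr_gate: float = 1.0
) -> pd.DataFrame:
    """Onset- and offset-window AUC per category and channel.

    ERPs failing the plus/minus SNR gate (SNR < 1) are excluded here, as
    the gate applies to the sensory analysis only.
    """
    rows = []
    for cat, er in erps.items():
        if er.n_epochs == 0:
            continue
        if np.isfinite(er.snr) and er.snr < snr_gate:
            logger.info(
                "sensory gate: dropping %s/%s (SNR %.2f < %.2f)",
                raw.subject_id, cat, er.snr, snr_gate,
            )
            continue
        wins = resolve_windows(cat, raw.domain, raw.dimension).on_epoch()
        for ch_i, ch in enumerate(er.channels):
            for win_name in ("onset", "offset"):
                rows.append(
                    {
                        "subject": raw.subject_id,
                        "domain": raw.domain,
                        "dimension": raw.dimension,
                        "category": cat,
                        "duration_ms": STIMULUS_TABLE[cat][1],
                        "channel": ch,
                        "window": win_name,
                        "n_epochs": er.n_epochs,
                        "snr": er.snr,
                        "value": measures.auc(
                            er.data[ch_i], wins[win_name], er.sample_rate, er.t0_ms
                        ),
                    }
                )
    return pd.DataFrame(rows)


def mmr_auc_records(es: EpochSet, raw: RawRecording) -> pd.DataFrame:
    """Early- and late-window AUC of region-pooled difference waves.

    For each physical stimulus the deviant-role average minus the
    standard-role average is formed per channel, pooled into laterality
    regions, smoothed, and integrated over the early and late windows.
    """
    rows = []
    for cat in sorted(es.meta["category"].unique()):
        dev = es.select(((es.meta["category"] == cat) & (es.meta["role"] == ROLE_DEVIANT)).to_numpy())
        std = es.select(((es.meta["category"] == cat) & (es.meta["role"] == ROLE_STANDARD)).to_numpy())
        if dev.n_kept == 0 or std.n_kept == 0:
            logger.warning(
                "mmr: empty %s condition for %s/%s", cat, raw.subject_id, raw.dimension
            )
            continue
        coords = {"subject": raw.subject_id, "domain": raw.domain,
                  "dimension": raw.dimension, "category": cat}
        dev_er = preprocess.average(dev, {**coords, "role": "deviant"})
        std_er = preprocess.average(std, {**coords, "role": "standard"})
        diff = measures.difference_wave(dev_er, std_er)
        wins = resolve_windows(cat, raw.domain, raw.dimension).on_epoch()
        direction = deviant_direction_label(raw.dimension, cat)
        for region, chans in DEFAULT_REGIONS.laterality.items():
            wave = measures.pool_channels(diff.data, diff.channels, chans)
            wave = savgol_filter(wave, 21, 1)
            for win_name in ("early_mmr", "late_mmr"):
                rows.append(
                    {
                        "subject": raw.subject_id,
                        "domain": raw.domain,
                        "dimension": raw.dimension,
                        "category": cat,
                        "deviant": direction,
                        "region": region,
                        "window": win_name.replace("_mmr", ""),
                        "n_deviant": dev_er.n_epochs,
                        "n_standard": std_er.n_epochs,
                        "value": measures.auc(wave, wins[win_name], diff.sample_rate, diff.t0_ms),
                    }
                )
    return pd.DataFrame(rows)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full simulated experiment described by ``config``.

    Returns a result bundle (tables plus paths of everything written to
    ``outdir``).  A stage failure aborts with an error naming the stage;
    outputs of completed stages are retained on disk.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc: dict = {"recordings": [], "counts": {}, "empty_conditions": 0, "snr_rejected_erps": 0}

    recordings: list[RawRecording] = []
    for domain in config.domains:
        recordings.extend(
            _stage("simulate")(simulate_cohort)(
                n_subjects=config.n_subjects_per_domain,
                domain=domain,
                dimensions=config.dimensions,
                erp=config.erp,
                mmr=config.mmr,
                noise=config.noise,
                master_seed=config.master_seed + (0 if domain.startswith("speech") else 1),
                sample_rate=config.sample_rate,
                block_kwargs={"occurrences_per_length": config.occurrences_per_length},
            )
        )
    # subject ids must be unique across the between-subject domain groups
    for rec in recordings:
        rec.subject_id = f"{rec.domain[:2]}_{rec.subject_id}"

    sens_tables, mmr_tables = [], []
    for rec in recordings:
        es = _stage("preprocess")(preprocess_recording)(rec, config.reject_uv)
        erps = _stage("average")(sensory_erps)(es, rec)
        n_low_snr = sum(
            1 for er in erps.values()
            if er.n_epochs and np.isfinite(er.snr) and er.snr < config.snr_gate
        )
        qc["snr_rejected_erps"] += n_low_snr
        sens = _stage("measures")(sensory_auc_records)(erps, rec, config.snr_gate)
        mmr = _stage("measures")(mmr_auc_records)(es, rec)
        if len(sens):
            sens_tables.append(sens)
        if len(mmr):
            mmr_tables.append(mmr)
        qc["recordings"].append(
            {
                "subject": rec.subject_id,
                "domain": rec.domain,
                "dimension": rec.dimension,
                "events": len(rec.events),
                "epochs": len(es.meta),
                "kept": es.n_kept,
                "rejected": int(es.rejected.sum()),
                "dropped_edge": es.n_dropped_edge,
                "erp_snr": {c: (None if not np.isfinite(e.snr) else round(e.snr, 3))
                            for c, e in erps.items()},
            }
        )

    sens_df = pd.concat(sens_tables, ignore_index=True) if sens_tables else pd.DataFrame()
    mmr_df = pd.concat(mmr_tables, ignore_index=True) if mmr_tables else pd.DataFrame()
    sens_path = outdir / "auc_sensory.csv"
    mmr_path = outdir / "auc_mmr.csv"
    sens_df.to_csv(sens_path, index=False)
    mmr_df.to_csv(mmr_path, index=False)

    bundle: dict = {"qc": qc, "sensory_auc": sens_df, "mmr_auc": mmr_df,
                    "paths": {"sensory_auc": sens_path, "mmr_auc": mmr_path}}

    fits: dict = {}
    qc["skipped_fits"] = []

    def _fit(name: str, sub: pd.DataFrame, spec: stats.ModelSpec):
        """Fit one window's model; a design made degenerate by upstream
        gating (e.g. every surviving row at one factor level) is recorded
        as a skipped fit, not a pipeline failure."""
        try:
            return stats.AucMixedModel(sub, spec).fit()
        except ValueError as exc:
            if "aliased" in str(exc) or "2 subjects" in str(exc):
                logger.warning("fit %s skipped: %s", name, exc)
                qc["skipped_fits"].append({"model": name, "reason": str(exc)})
                return None
            raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    enough_domains = len(set(config.domains)) > 1
    if len(sens_df) and enough_domains:
        for window, spec in (("onset", stats.onset_model_spec()),
                             ("offset", stats.offset_model_spec())):
            res = _fit(f"{window}_erp", sens_df[sens_df["window"] == window], spec)
            if res is None:
                continue
            fits[f"{window}_erp"] = res
            path = outdir / f"coef_{window}_erp.csv"
            res.coef_table().to_csv(path)
            bundle["paths"][f"coef_{window}_erp"] = path
    if len(mmr_df) and enough_domains:
        for window in ("early", "late"):
            res = _fit(f"{window}_mmr", mmr_df[mmr_df["window"] == window],
                       stats.mmr_model_spec())
            if res is None:
                continue
            fits[f"{window}_mmr"] = res
            res.coef_table().to_csv(outdir / f"coef_{window}_mmr.csv")
            cells = res.compare_deviants()
            cells.to_csv(outdir / f"cells_{window}_mmr.csv", index=False)
            bundle["paths"][f"cells_{window}_mmr"] = outdir / f"cells_{window}_mmr.csv"
    if not len(mmr_df) or not len(sens_df):
        qc["empty_conditions"] = int(not len(mmr_df)) + int(not len(sens_df))
        logger.warning("run_pipeline: empty AUC table(s); model fits skipped")

    bundle["fits"] = fits
    qc_path = outdir / "qc.json"
    qc_path.write_text(json.dumps(qc, indent=2))
    bundle["paths"]["qc"] = qc_path
    return bundle
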