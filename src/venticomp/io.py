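"""File formats: waveform CSV + JSON sidecar, breath tables, summaries.

Waveform CSV columns: ``time_s,pressure_mbar,flow_ml_min``. The sidecar JSON
carries recipient, weight, scenario, resuscitator settings and seed; a
ground-truth log CSV (per-breath injected leak fraction, compliance,
obstruction flag) accompanies simulated episodes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .breath_analysis import VentilationSequence
from .ventsim import Episode, ResuscitatorSettings, WaveformRecord

__all__ = ["write_episode", "read_waveform", "write_breath_table",
           "write_sequence_summaries", "read_sequence_summaries"]


def _settings_to_dict(settings: ResuscitatorSettings | None) -> dict | None:
    return dataclasses.asdict(settings) if settings is not None else None


def write_episode(episode: Episode, out_dir: str | Path) -> Path:
    """Write waveform CSV, metadata JSON and ground-truth log CSV.

    Returns the waveform CSV path (``<episode_id>.csv``); the sidecars are
    ``<episode_id>.meta.json`` and ``<episode_id>.truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = out_dir / episode.episode_id
    wf_path = base.with_suffix(".csv")
    episode.record.to_frame().to_csv(wf_path, index=False,
                                     float_format="%.6g")
    truth_path = base.with_suffix(".truth.csv")
    episode.truth.to_csv(truth_path, index=False, float_format="%.8g")
    meta = {
        "episode_id": episode.episode_id,
        "recipient": episode.recipient,
        "weight_kg": episode.weight,
        "scenario": episode.scenario,
        "seed": episode.record.metadata.get("seed"),
        "settings": _settings_to_dict(episode.record.metadata.get("settings")),
        "success_time_s": episode.success_time,
        "ppv_time_s": episode.ppv_time,
        "truth_log": truth_path.name,
    }
    base.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return wf_path


def read_waveform(path: str | Path) -> tuple[WaveformRecord, dict]:
    """Read a waveform CSV (+ sidecar metadata JSON if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "pressure_mbar", "flow_ml_min"} - set(df.columns)
    if missing:
        raise ValueError(f"waveform CSV missing columns: {sorted(missing)}")
    meta_path = path.with_suffix("").with_suffix(".meta.json") \
        if path.suffixes[-1] == ".csv" else None
    meta: dict = {}
    if meta_path is not None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
    record = WaveformRecord(df["time_s"].to_numpy(),
                            df["pressure_mbar"].to_numpy(),
                            df["flow_ml_min"].to_numpy(), dict(meta))
    return record, meta


def write_breath_table(sequences: list[VentilationSequence],
                       path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [s.to_frame() for s in sequences if s.n_breaths]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def write_sequence_summaries(sequences: list[VentilationSequence],
                             path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([s.summary() for s in sequences], indent=2))
    return path


def read_sequence_summaries(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def to_jsonable(obj):
    """Recursively convert numpy scalars/arrays for json.dumps."""
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
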