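"""File formats: session tables, raw signals, timelines, event logs.

A band-power session is a plain CSV with columns ``timestamp_s``,
``tp9_delta`` ... ``tp10_gamma`` (electrode-major, band order delta,
theta, alpha, beta, gamma) and ``label`` in {internal, external, none},
plus a companion ``<name>.meta.json`` carrying the plan, generator
parameters, seed, format version and a config hash. Raw signals use a
per-channel CSV with the sampling rate in the metadata. Timeline and
event-log CSVs embed the config hash and seed in a leading ``#`` comment
line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .appsim import EventLog
from .bands import ELECTRODES, FEATURE_COLUMNS
from .decider import PauseTimeline
from .frames import FrameStream, RawEegSegment
from .plans import SessionPlan
from .synth import GeneratorParams

FORMAT_VERSION = 1

__all__ = [
    "config_hash",
    "write_session",
    "read_session",
    "write_raw",
    "read_raw",
    "write_timeline",
    "read_timeline",
    "write_events",
    "read_events",
]


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_session(
    path: str | Path,
    stream: FrameStream,
    plan: SessionPlan | None = None,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> None:
    path = Path(path)
    stream.to_dataframe().to_csv(path, index=False, float_format="%.10g")
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": "bandpower_session",
        "n_frames": len(stream),
        "plan": plan.to_dict() if plan else None,
        "params": params.to_dict() if params else None,
        "seed": seed if seed is not None else (plan.seed if plan else None),
    }
    meta["config_hash"] = config_hash({k: v for k, v in meta.items()})
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> tuple[FrameStream, dict]:
    """Read a session CSV (+ metadata if present); errors name missing columns."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    stream = FrameStream.from_dataframe(df)  # validates mandatory columns
    meta: dict = {}
    if _meta_path(path).exists():
        meta = json.loads(_meta_path(path).read_text())
        if meta.get("format_version", FORMAT_VERSION) != FORMAT_VERSION:
            raise ValueError(f"unsupported session format version {meta['format_version']}")
    return stream, meta


def session_plan_from_meta(meta: dict) -> SessionPlan | None:
    return SessionPlan.from_dict(meta["plan"]) if meta.get("plan") else None


def write_raw(
    path: str | Path,
    segment: RawEegSegment,
    plan: SessionPlan | None = None,
    seed: int | None = None,
) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"timestamp_s": segment.sample_times()}
        | {e.lower(): segment.data[i] for i, e in enumerate(segment.channels)}
    )
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": "raw_eeg",
        "fs": segment.fs,
        "channels": list(segment.channels),
        "n_samples": segment.n_samples,
        "plan": plan.to_dict() if plan else None,
        "seed": seed,
    }
    meta["config_hash"] = config_hash(meta)
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_raw(path: str | Path) -> tuple[RawEegSegment, dict]:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    meta: dict = {}
    fs = 256.0
    channels = ELECTRODES
    if _meta_path(path).exists():
        meta = json.loads(_meta_path(path).read_text())
        fs = float(meta.get("fs", fs))
        channels = tuple(meta.get("channels", channels))
    missing = [c.lower() for c in channels if c.lower() not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
    data = np.stack([df[c.lower()].to_numpy(float) for c in channels])
    start = float(df["timestamp_s"].iloc[0]) if "timestamp_s" in df.columns else 0.0
    return RawEegSegment(data=data, fs=fs, channels=channels, start_time=start), meta


def _write_csv_with_header(path: Path, df: pd.DataFrame, meta: dict | None) -> None:
    with open(path, "w") as fh:
        if meta:
            items = " ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"# {items}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def write_timeline(path: str | Path, timeline: PauseTimeline, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {"timestamp_s": timeline.times, "paused": timeline.paused.astype(int)}
    )
    _write_csv_with_header(Path(path), df, meta)


def read_timeline(path: str | Path) -> PauseTimeline:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("timestamp_s", "paused") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
    return PauseTimeline(df["timestamp_s"].to_numpy(float), df["paused"].to_numpy(bool))


def write_events(path: str | Path, log: EventLog, meta: dict | None = None) -> None:
    df = pd.DataFrame(log.events, columns=["timestamp_s", "kind"])
    header = {"duration_s": log.duration} | (meta or {})
    _write_csv_with_header(Path(path), df, header)


def read_events(path: str | Path) -> EventLog:
    first = Path(path).read_text().splitlines()[0]
    duration = None
    if first.startswith("#"):
        for item in first[1:].split():
            k, _, v = item.partition("=")
            if k == "duration_s":
                duration = float(v)
    df = pd.read_csv(path, comment="#")
    events = [(float(t), str(k)) for t, k in zip(df["timestamp_s"], df["kind"])]
    if duration is None:
        duration = events[-1][0] if events else 0.0
    return EventLog(events=events, duration=duration)
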