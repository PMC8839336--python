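"""Plain-text recording exchange: signals CSV, events CSV, JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EventSchedule, SprPairRecording

__all__ = ["FormatError", "write_recording", "read_recording"]

SIGNAL_COLUMNS = ["time_s", "spr_left_mV", "spr_right_mV", "ecg_mV"]
EVENT_COLUMNS = ["start_s", "end_s", "kind"]


class FormatError(ValueError):
    """Malformed recording file."""


def write_recording(rec: SprPairRecording, out_dir: str | Path,
                    stem: str | None = None) -> dict[str, Path]:
    """Write a recording as ``<stem>_signals.csv``, ``<stem>_events.csv``
    and ``<stem>_meta.json``; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{rec.subject_id}_{rec.scenario}"
    paths = {
        "signals": out_dir / f"{stem}_signals.csv",
        "events": out_dir / f"{stem}_events.csv",
        "meta": out_dir / f"{stem}_meta.json",
    }
    pd.DataFrame({
        "time_s": rec.t, "spr_left_mV": rec.spr_left,
        "spr_right_mV": rec.spr_right, "ecg_mV": rec.ecg,
    }).to_csv(paths["signals"], index=False, float_format="%.6f")
    pd.DataFrame(
        [(s, s + d, "stress") for s, d, _a in rec.events.events],
        columns=EVENT_COLUMNS,
    ).to_csv(paths["events"], index=False)
    meta = {
        "subject_id": rec.subject_id,
        "scenario": rec.scenario,
        "fs": rec.fs,
        "sections": [[s, e, tag] for s, e, tag in rec.sections],
        "seed": rec.seed,
        "event_amplitudes_mv": [a for _s, _d, a in rec.events.events],
        "duration_s": rec.duration_s,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_recording(signal_path: str | Path, events_path: str | Path | None,
                   meta_path: str | Path) -> SprPairRecording:
    """Read and validate a recording written by :func:`write_recording`.

    Checks the column set, time-axis uniformity, agreement between the
    sidecar's fs and the time column (1% tolerance), and rejects NaN runs
    longer than 1 s; shorter NaN runs are linearly interpolated.
    """
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(signal_path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{signal_path}: missing columns {missing}")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{signal_path}: too few samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-3 * np.median(dt) + 1e-9:
        bad = int(np.argmax(np.abs(dt - np.median(dt))))
        raise FormatError(f"{signal_path}: non-uniform time axis near line {bad + 2}")
    fs_file = 1.0 / float(np.median(dt))
    fs_meta = float(meta["fs"])
    if abs(fs_file - fs_meta) > 0.01 * fs_meta:
        raise FormatError(
            f"{signal_path}: time column implies fs={fs_file:.3f}, sidecar says {fs_meta}")

    series = {}
    for col in SIGNAL_COLUMNS[1:]:
        x = df[col].to_numpy(dtype=float)
        nan = np.isnan(x)
        if nan.any():
            run, longest = 0, 0
            for flag in nan:
                run = run + 1 if flag else 0
                longest = max(longest, run)
            if longest / fs_meta > 1.0:
                raise FormatError(f"{signal_path}: NaN run longer than 1 s in {col}")
            idx = np.arange(len(x))
            x = np.interp(idx, idx[~nan], x[~nan])
        series[col] = x

    events: list[tuple[float, float, float]] = []
    if events_path is not None and Path(events_path).exists():
        ev = pd.read_csv(events_path)
        if len(ev):
            missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
            if missing:
                raise FormatError(f"{events_path}: missing columns {missing}")
            amps = meta.get("event_amplitudes_mv") or [0.0] * len(ev)
            for (_, row), amp in zip(ev.iterrows(), amps):
                events.append((float(row["start_s"]),
                               float(row["end_s"]) - float(row["start_s"]), float(amp)))
    schedule = EventSchedule(events=events,
                             recording_duration_s=float(meta.get("duration_s", t[-1] + 1 / fs_meta)))
    return SprPairRecording(
        t=t, spr_left=series["spr_left_mV"], spr_right=series["spr_right_mV"],
        ecg=series["ecg_mV"], events=schedule,
        sections=[(float(s), float(e), str(tag)) for s, e, tag in meta.get("sections", [])],
        subject_id=str(meta["subject_id"]), scenario=str(meta["scenario"]),
        fs=fs_meta, seed=meta.get("seed"),
    )
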