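"""Reading and writing session files, trigger logs, traces, and reports.

A session is a delimited-text pair: ``<name>.csv`` with a ``time_s`` column
plus one column per sensor channel, and a ``<name>.json`` sidecar holding the
exercise metadata (exercise id, active channel, units, nominal sampling rate,
movement minimum, directionality).  Rest-calibration recordings use the same
format with exercise_id ``"rest"``.

Timestamps are serialized as seconds from session start with 6 decimal
places — sub-sample precision at 60 Hz without float drift — which also makes
repeated runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import CohortSummary, SessionMetrics
from .signal_core import ExerciseConfig, RawSignal
from .triggering import TriggerEvent

_FLOAT_FMT = "%.6f"


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_session(
    csv_path: str | Path,
    signals: dict[str, RawSignal] | RawSignal,
    config: ExerciseConfig,
) -> None:
    """Write a session CSV plus its JSON metadata sidecar."""
    csv_path = Path(csv_path)
    if isinstance(signals, RawSignal):
        signals = {signals.channel_label: signals}
    first = next(iter(signals.values()))
    frame = {"time_s": first.timestamps}
    for label, sig in signals.items():
        if len(sig) != len(first):
            raise ValueError("all channels must share the same time base")
        frame[label] = sig.values
    pd.DataFrame(frame).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "exercise_id": config.exercise_id,
        "channel_label": config.channel_label,
        "units": config.units,
        "sampling_rate_hz": first.sampling_rate,
        "movement_minimum": config.movement_minimum,
        "directionality": config.directionality,
    }
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_session(csv_path: str | Path) -> tuple[dict[str, RawSignal], ExerciseConfig]:
    """Read a session CSV + sidecar into validated signals and a config.

    Raises distinct errors for a missing sidecar, a channel named in the
    sidecar but absent from the CSV, NaN values (naming the column), and
    non-monotone timestamps (naming the row).
    """
    csv_path = Path(csv_path)
    side = sidecar_path(csv_path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {side}")
    meta = json.loads(side.read_text())
    df = pd.read_csv(csv_path)
    if "time_s" not in df.columns:
        raise ValueError(f"{csv_path}: missing required column 'time_s'")
    for col in df.columns:
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise ValueError(f"{csv_path}: NaN in column {col!r} at row {row}")
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) > 1 and np.any(np.diff(time) <= 0):
        row = int(np.argmax(np.diff(time) <= 0)) + 1
        raise ValueError(f"{csv_path}: time_s not strictly increasing at row {row}")
    config = ExerciseConfig(
        exercise_id=meta["exercise_id"],
        channel_label=meta["channel_label"],
        movement_minimum=float(meta.get("movement_minimum", 0.0)),
        directionality=meta.get("directionality", "both"),
        units=meta.get("units", ""),
    )
    rate = float(meta.get("sampling_rate_hz", 60.0))
    signals = {
        col: RawSignal(time, df[col].to_numpy(dtype=float), col, rate)
        for col in df.columns
        if col != "time_s"
    }
    if config.channel_label not in signals:
        raise ValueError(
            f"{csv_path}: sidecar names channel {config.channel_label!r} "
            f"but the CSV has {sorted(signals)}"
        )
    return signals, config


def write_trigger_log(path: str | Path, events: list[TriggerEvent]) -> None:
    """Trigger log CSV: time_s, paired_value, threshold, algorithm, direction."""
    rows = [
        {
            "time_s": ev.time,
            "paired_value": ev.paired_value,
            "threshold": math.nan if ev.threshold_at_trigger is None else ev.threshold_at_trigger,
            "algorithm": ev.algorithm,
            "direction": ev.direction,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows, columns=["time_s", "paired_value", "threshold", "algorithm", "direction"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trigger_log(path: str | Path) -> list[TriggerEvent]:
    # keep_default_na so the literal direction "n/a" survives as a string
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    events = []
    for _, row in df.iterrows():
        thr = row["threshold"]
        events.append(
            TriggerEvent(
                time=float(row["time_s"]),
                paired_value=float(row["paired_value"]),
                threshold_at_trigger=None if pd.isna(thr) else float(thr),
                algorithm=str(row["algorithm"]),
                direction=str(row["direction"]),
            )
        )
    return events


def write_threshold_trace(path: str | Path, trace: dict[str, np.ndarray]) -> None:
    """Per-sample threshold trace CSV (threshold_pos/threshold_neg, blank when n/a)."""
    pd.DataFrame(
        {
            "time_s": trace["time_s"],
            "threshold_pos": trace["threshold_pos"],
            "threshold_neg": trace["threshold_neg"],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_annotations(path: str | Path, annotations: pd.DataFrame) -> None:
    annotations.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_session_metrics(path: str | Path, rows: list[SessionMetrics]) -> None:
    """Per-session metrics report, one row per session x algorithm."""
    records = []
    for m in rows:
        rec = dataclasses.asdict(m)
        rec["isi_values"] = ";".join(f"{x:.6f}" for x in m.isi_values)
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_cohort_summary(path: str | Path, summaries: dict[str, CohortSummary]) -> None:
    """Cohort summary JSON: one entry per algorithm/quantity."""
    payload = {name: dataclasses.asdict(s) for name, s in summaries.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
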