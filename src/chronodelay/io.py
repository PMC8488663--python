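"""CSV / JSON readers and writers for the pipeline's file contracts.

All CSVs are comma-separated UTF-8 with a header row and '.' decimals.
Activity recordings travel as a counts CSV (``bin_start_s,count``) plus a
JSON sidecar holding bin width, ZT origin, the lighting schedule and, for
synthetic data, the ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schedules import LightSchedule, LightSegment
from .synthetic.activity import ActivityRecording
from .synthetic.bioluminescence import BioluminescenceTrace


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def schedule_to_dict(schedule: LightSchedule) -> list:
    return [
        {"day": d, "protocol": label,
         "segments": [{"start_zt": s.start_zt, "end_zt": s.end_zt, "lux": s.lux}
                      for s in segs]}
        for d, (label, segs) in enumerate(schedule.days)
    ]


def schedule_from_dict(days: list) -> LightSchedule:
    out = []
    for entry in sorted(days, key=lambda e: e["day"]):
        segs = [LightSegment(s["start_zt"], s["end_zt"], s["lux"]) for s in entry["segments"]]
        out.append((entry.get("protocol", "LD"), segs))
    return LightSchedule(days=out)


def write_activity(recording: ActivityRecording, csv_path, include_truth: bool = True) -> None:
    csv_path = Path(csv_path)
    n = len(recording.counts)
    pd.DataFrame({
        "bin_start_s": np.arange(n) * recording.bin_width_s,
        "count": recording.counts,
    }).to_csv(csv_path, index=False)
    sidecar = {
        "bin_width_s": recording.bin_width_s,
        "start_zt_h": recording.start_zt_h,
        "schedule": schedule_to_dict(recording.schedule),
    }
    if include_truth and recording.ground_truth:
        truth = {k: v for k, v in recording.ground_truth.items()
                 if k not in ("active_mask", "dim_mask")}
        sidecar["ground_truth"] = _jsonable(truth)
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_activity(csv_path) -> ActivityRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return ActivityRecording(
        counts=df["count"].to_numpy(dtype=np.int64),
        schedule=schedule_from_dict(meta["schedule"]),
        bin_width_s=int(meta["bin_width_s"]),
        start_zt_h=float(meta["start_zt_h"]),
        ground_truth=meta.get("ground_truth", {}),
    )


def write_bioluminescence(trace: BioluminescenceTrace, csv_path) -> None:
    pd.DataFrame({
        "minute": np.arange(trace.n_minutes),
        "shutter": np.where(trace.shutter_open, "open", "closed"),
        "counts": trace.counts,
    }).to_csv(csv_path, index=False)


def read_bioluminescence(csv_path) -> BioluminescenceTrace:
    df = pd.read_csv(csv_path)
    return BioluminescenceTrace(
        counts=df["counts"].to_numpy(dtype=np.int64),
        shutter_open=(df["shutter"] == "open").to_numpy(),
    )


def write_qpcr(table: pd.DataFrame, csv_path) -> None:
    table.to_csv(csv_path, index=False)


def read_qpcr(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    required = {"sample_id", "tissue", "condition", "zt", "gene", "role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df


def write_trials(trials: pd.DataFrame, csv_path) -> None:
    trials.to_csv(csv_path, index=False)


def read_trials(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
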