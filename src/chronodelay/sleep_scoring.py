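"""Immobility-defined sleep scoring from PIR counts.

A 10-s bin is scored asleep (1) iff it belongs to a maximal run of
consecutive zero-count bins at least 4 bins (40 s) long; otherwise awake (0).
Sustained immobility of >= 40 s is a validated behavioural proxy for
EEG-defined sleep in mice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_BOUT_BINS = 4
BIN_S = 10


@dataclass
class SleepSeries:
    """Per-bin 0/1 sleep state aligned to a parent activity recording."""

    state: np.ndarray
    bin_width_s: int = BIN_S
    start_zt_h: float = 0.0


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs."""
    if mask.size == 0:
        return np.empty(0, int), np.empty(0, int)
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


def score_sleep(recording) -> SleepSeries:
    """Score sleep from an ActivityRecording (or a raw count array)."""
    if hasattr(recording, "counts"):
        counts = np.asarray(recording.counts)
        bw = recording.bin_width_s
        z0 = recording.start_zt_h
    else:
        counts, bw, z0 = np.asarray(recording), BIN_S, 0.0
    immobile = counts == 0
    state = np.zeros(len(counts), dtype=np.int8)
    starts, lengths = _runs(immobile)
    for s, ln in zip(starts, lengths):
        if ln >= MIN_BOUT_BINS:
            state[s:s + ln] = 1
    return SleepSeries(state=state, bin_width_s=bw, start_zt_h=z0)


def sleep_bouts(series: SleepSeries) -> list:
    """Maximal sleep runs as (start_bin, length_bins); lengths are >= 4."""
    starts, lengths = _runs(series.state.astype(bool))
    return list(zip(starts.tolist(), lengths.tolist()))


def sleep_proportion(series: SleepSeries, start_h: float, end_h: float) -> float:
    """Fraction of bins asleep in the window [start_h, end_h) (absolute ZT)."""
    bw_h = series.bin_width_s / 3600.0
    i0 = int(round((start_h - series.start_zt_h) / bw_h))
    i1 = int(round((end_h - series.start_zt_h) / bw_h))
    if i1 <= i0:
        raise ValueError("empty window")
    if i0 < 0 or i1 > len(series.state):
        raise ValueError("window outside the recording")
    return float(series.state[i0:i1].mean())


def prior_sleep(series: SleepSeries, event_time_h: float, width_h: float) -> float:
    """Sleep proportion over the ``width_h`` hours preceding ``event_time_h``.

    Returns NaN when the recording does not reach back far enough.
    """
    start = event_time_h - width_h
    if start < series.start_zt_h - 1e-9:
        return float("nan")
    return sleep_proportion(series, start, event_time_h)


def binned_summary(series: SleepSeries, bin_width_h: float = 4.0) -> pd.DataFrame:
    """Per (day, ZT bin) sleep proportion and bout-duration summary.

    Proportion counts per-bin membership; each bout is assigned to the ZT bin
    containing its onset for the duration statistic, so the two describe
    slightly different partitions by design.  Bins without any bout onset
    report NaN mean duration.
    """
    bw_h = series.bin_width_s / 3600.0
    bins_per = int(round(bin_width_h / bw_h))
    n = len(series.state)
    t = series.start_zt_h + np.arange(n) * bw_h
    day = (t // 24.0).astype(int)
    ztbin = ((t - 24.0 * day) // bin_width_h).astype(int) * int(bin_width_h)

    df = pd.DataFrame({"day": day, "zt_bin": ztbin, "state": series.state})
    prop = df.groupby(["day", "zt_bin"])["state"].agg(["mean", "size"])

    starts, lengths = _runs(series.state.astype(bool))
    bout_day = day[starts] if len(starts) else np.empty(0, int)
    bout_bin = ztbin[starts] if len(starts) else np.empty(0, int)
    bouts = pd.DataFrame({"day": bout_day, "zt_bin": bout_bin,
                          "dur_s": lengths * series.bin_width_s})
    bstats = bouts.groupby(["day", "zt_bin"])["dur_s"].agg(["mean", "count"])

    out = prop.join(bstats, how="left", lsuffix="_p")
    out.columns = ["proportion", "n_bins", "mean_bout_s", "bout_count"]
    out["bout_count"] = out["bout_count"].fillna(0).astype(int)
    out = out.drop(columns=["n_bins"]).reset_index()
    # drop trailing partial bins
    full = df.groupby(["day", "zt_bin"])["state"].size() == bins_per
    out = out[full.values].reset_index(drop=True)
    return out
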