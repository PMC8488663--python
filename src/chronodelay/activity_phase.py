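"""Activity phase markers from moving-average crossings.

Daily activity onset and offset are the crossings of a short (3-h) and a long
(24-h) moving average of the 1-h-smoothed PIR series: onset where the short
average first exceeds the long one within a day window, offset where it last
drops below it after the onset.  The daily midpoint is the time at which total
activity in the preceding 8 h equals that in the subsequent 8 h.  Day windows
run ZT6-ZT30 so the nocturnal bout is never split at midnight.

All moving averages are centred, and positions where the full window does not
fit are undefined (NaN), never zero-padded.  Sign changes through exact-zero
runs register at the first bin where the difference becomes nonzero with the
opposite sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BIN_S = 10
BINS_PER_DAY = 8640
BINS_PER_HOUR = 360
DAY_WINDOW = (6.0, 30.0)


def moving_average(series, window_bins: int) -> np.ndarray:
    """Centred moving average; NaN wherever the full window does not fit.

    Even windows are widened by one bin so the window straddles the centre
    bin symmetrically.  NaNs in the input poison every window touching them.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if window_bins % 2 == 0:
        window_bins += 1
    x = np.asarray(series, dtype=float)
    n = len(x)
    out = np.full(n, np.nan)
    if window_bins > n:
        warnings.warn("moving-average window longer than series; all undefined")
        return out
    h = window_bins // 2
    valid = np.isfinite(x)
    xz = np.where(valid, x, 0.0)
    cs = np.concatenate(([0.0], np.cumsum(xz)))
    cv = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    i = np.arange(h, n - h)
    sums = cs[i + h + 1] - cs[i - h]
    nvalid = cv[i + h + 1] - cv[i - h]
    vals = np.where(nvalid == window_bins, sums / window_bins, np.nan)
    out[h:n - h] = vals
    return out


@dataclass
class SmoothedActivity:
    """1-h base smoothing plus the short/long averages and their difference."""

    base: np.ndarray
    short: np.ndarray
    long: np.ndarray
    delta: np.ndarray
    bin_width_s: int = BIN_S
    start_zt_h: float = 0.0

    @classmethod
    def from_counts(cls, counts, bin_width_s: int = BIN_S, start_zt_h: float = 0.0,
                    base_h: float = 1.0, short_h: float = 3.0, long_h: float = 24.0):
        per_h = int(round(3600 / bin_width_s))
        base = moving_average(counts, int(base_h * per_h))
        short = moving_average(base, int(short_h * per_h))
        long_ = moving_average(base, int(long_h * per_h))
        return cls(base=base, short=short, long=long_, delta=short - long_,
                   bin_width_s=bin_width_s, start_zt_h=start_zt_h)

    @classmethod
    def from_recording(cls, recording, **kw):
        return cls.from_counts(recording.counts, recording.bin_width_s,
                               recording.start_zt_h, **kw)


def crossings(delta) -> list:
    """Sign changes of the short-long difference as (index, direction).

    direction +1: upward (short average rises through the long one);
    direction -1: downward.  Exact zeros are skipped: the crossing registers
    at the first subsequent nonzero bin of opposite sign.
    """
    d = np.asarray(delta, dtype=float)
    nz = np.flatnonzero(np.isfinite(d) & (d != 0.0))
    if len(nz) < 2:
        return []
    s = np.sign(d[nz])
    flips = np.flatnonzero(s[1:] != s[:-1]) + 1
    return [(int(nz[j]), int(s[j])) for j in flips]


def _bin_time_h(index, bin_width_s: float, start_zt_h: float) -> float:
    return start_zt_h + (index + 0.5) * bin_width_s / 3600.0


def _assign_daily(cross, n_days: int, bin_width_s: float, start_zt_h: float):
    """Split crossings into per-day lists over ZT[6, 30) windows."""
    per_day = [[] for _ in range(n_days)]
    for idx, direction in cross:
        t = _bin_time_h(idx, bin_width_s, start_zt_h)
        d = int((t - DAY_WINDOW[0]) // 24.0)
        if 0 <= d < n_days:
            per_day[d].append((t - 24.0 * d, direction))
    return per_day


def daily_onset_offset(sm: SmoothedActivity, n_days: int | None = None) -> pd.DataFrame:
    """Per-day onset (first upward crossing) and offset (last downward after it).

    Times are continuous local hours in [6, 30); missing markers are NaN.
    """
    if n_days is None:
        n_days = len(sm.delta) // int(24 * 3600 / sm.bin_width_s)
    cross = crossings(sm.delta)
    if not cross:
        warnings.warn("no short/long crossings found; all markers missing")
    per_day = _assign_daily(cross, n_days, sm.bin_width_s, sm.start_zt_h)
    rows = []
    for d, events in enumerate(per_day):
        # only report a day whose full ZT[6, 30) window is observable: with
        # undefined bins at the window edges the "first"/"last" crossing is
        # not identified (edge days of a recording)
        i0 = int((24.0 * d + DAY_WINDOW[0] - sm.start_zt_h) * 3600 / sm.bin_width_s)
        i1 = int((24.0 * d + DAY_WINDOW[1] - sm.start_zt_h) * 3600 / sm.bin_width_s)
        observable = (i0 >= 0 and i1 <= len(sm.delta)
                      and np.isfinite(sm.delta[i0]) and np.isfinite(sm.delta[i1 - 1]))
        if not observable:
            rows.append((d, np.nan, np.nan))
            continue
        onset = next((t for t, dr in events if dr > 0), np.nan)
        offset = np.nan
        if np.isfinite(onset):
            downs = [t for t, dr in events if dr < 0 and t > onset]
            if downs:
                offset = downs[-1]
        rows.append((d, onset, offset))
    return pd.DataFrame(rows, columns=["day", "onset_zt", "offset_zt"])


def daily_midpoint(counts, bin_width_s: int = BIN_S, start_zt_h: float = 0.0,
                   half_window_h: float = 8.0) -> pd.DataFrame:
    """Per-day activity-balance midpoint.

    The balance statistic at bin i is (activity in the preceding 8 h) minus
    (activity in the subsequent 8 h); the midpoint is its upward zero
    crossing, assigned to day windows like the onsets.
    """
    x = np.asarray(counts, dtype=float)
    w = int(round(half_window_h * 3600 / bin_width_s))
    n = len(x)
    bins_per_day = int(24 * 3600 / bin_width_s)
    n_days = n // bins_per_day
    delta = np.full(n, np.nan)
    if n >= 2 * w:
        cs = np.concatenate(([0.0], np.cumsum(x)))
        i = np.arange(w, n - w + 1)
        delta_vals = (cs[i] - cs[i - w]) - (cs[i + w] - cs[i])
        delta[w:n - w + 1] = delta_vals
    ups = np.array([idx for idx, dr in crossings(delta) if dr > 0], dtype=int)
    rows = []
    for d in range(n_days):
        # day window ZT[6, 30); the midpoint is the upward crossing that ends
        # the deepest negative balance excursion (count noise while both 8-h
        # windows cover rest can produce shallow spurious sign changes)
        i0 = int((24.0 * d + DAY_WINDOW[0] - start_zt_h) * 3600 / bin_width_s)
        i1 = int((24.0 * d + DAY_WINDOW[1] - start_zt_h) * 3600 / bin_width_s)
        i0, i1 = max(i0, 0), min(i1, n)
        win = delta[i0:i1]
        mid = np.nan
        if i1 > i0 and np.isfinite(win).all() and np.nanmin(win) < 0:
            trough = i0 + int(np.nanargmin(win))
            cand = ups[(ups > trough) & (ups < i1)]
            if len(cand):
                mid = _bin_time_h(int(cand[0]), bin_width_s, start_zt_h) - 24.0 * d
        rows.append((d, mid))
    return pd.DataFrame(rows, columns=["day", "midpoint_zt"])


def phase_marker_table(recording) -> pd.DataFrame:
    """Onset, midpoint and offset per day for one recording."""
    sm = SmoothedActivity.from_recording(recording)
    oo = daily_onset_offset(sm, recording.n_days)
    mid = daily_midpoint(recording.counts, recording.bin_width_s, recording.start_zt_h)
    return oo.merge(mid, on="day")[["day", "onset_zt", "midpoint_zt", "offset_zt"]]


def unwrap_markers(values) -> np.ndarray:
    """Keep successive daily marker values within +/-12 h of each other."""
    v = np.asarray(values, dtype=float)
    out = v.copy()
    last = np.nan
    for i, x in enumerate(v):
        if not np.isfinite(x):
            continue
        if np.isfinite(last):
            x = x + 24.0 * round((last - x) / 24.0)
        out[i] = x
        last = x
    return out


@dataclass
class PhaseDelayEstimate:
    marker: str
    mean_h: float
    sem_h: float
    per_animal: np.ndarray


def phase_delay(tables: dict, marker: str, baseline_days, treatment_days) -> PhaseDelayEstimate:
    """Group delay of one marker: mean(treatment days) - mean(baseline days).

    ``tables`` maps animal id -> phase_marker_table output.  Each animal's
    marker sequence is unwrapped before averaging; animals with no valid
    marker in either day set are excluded with a warning.
    """
    baseline_days = set(baseline_days)
    treatment_days = set(treatment_days)
    if not baseline_days or not treatment_days:
        raise ValueError("both day sets must be non-empty")
    col = f"{marker}_zt"
    deltas = []
    for animal, tab in sorted(tables.items()):
        vals = unwrap_markers(tab[col].to_numpy())
        days = tab["day"].to_numpy()
        b = vals[np.isin(days, list(baseline_days)) & np.isfinite(vals)]
        t = vals[np.isin(days, list(treatment_days)) & np.isfinite(vals)]
        if len(b) == 0 or len(t) == 0:
            warnings.warn(f"animal {animal}: no valid {marker} in a day set; excluded")
            continue
        deltas.append(t.mean() - b.mean())
    deltas = np.asarray(deltas)
    if len(deltas) == 0:
        raise ValueError("no animal had valid markers in both day sets")
    sem = deltas.std(ddof=1) / np.sqrt(len(deltas)) if len(deltas) > 1 else np.nan
    return PhaseDelayEstimate(marker=marker, mean_h=float(deltas.mean()),
                              sem_h=float(sem), per_animal=deltas)


def free_run_period(marker_table: pd.DataFrame, marker: str = "onset") -> float:
    """Free-running period tau from the daily drift of a marker under DD.

    tau = 24 + slope of the least-squares regression of the unwrapped marker
    time (hours) on day index; requires >= 4 valid days, else NaN.
    """
    col = f"{marker}_zt"
    vals = unwrap_markers(marker_table[col].to_numpy())
    days = marker_table["day"].to_numpy(dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 4:
        warnings.warn("fewer than 4 valid markers; free-running period undefined")
        return float("nan")
    slope = stats.linregress(days[ok], vals[ok]).slope
    return 24.0 + float(slope)
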