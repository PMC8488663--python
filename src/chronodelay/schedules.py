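"""Lighting schedules for circadian housing protocols.

A :class:`LightSchedule` is a per-day list of non-overlapping lux segments on
the Zeitgeber-time axis (ZT0 = lights-on).  Four standard protocols are
supported:

``LD``
    12 h at 200 lx (ZT0-12), 12 h darkness.
``DLE``
    12 h at 200 lx, then a 4 h dim (20 lx) evening (ZT12-16), 8 h darkness.
``LD16_8``
    16 h at 200 lx (ZT0-16), 8 h darkness -- a long-day photoperiod.
``DD``
    constant darkness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROTOCOL_SEGMENTS = {
    "LD": [(0.0, 12.0, 200.0), (12.0, 24.0, 0.0)],
    "DLE": [(0.0, 12.0, 200.0), (12.0, 16.0, 20.0), (16.0, 24.0, 0.0)],
    "LD16_8": [(0.0, 16.0, 200.0), (16.0, 24.0, 0.0)],
    "DD": [(0.0, 24.0, 0.0)],
}


@dataclass(frozen=True)
class LightSegment:
    start_zt: float
    end_zt: float
    lux: float

    def __post_init__(self):
        if not 0.0 <= self.start_zt < 24.0:
            raise ValueError(f"segment start {self.start_zt} outside [0, 24)")
        if self.end_zt <= self.start_zt or self.end_zt > 24.0:
            raise ValueError(f"segment end {self.end_zt} invalid")
        if self.lux < 0:
            raise ValueError("lux must be non-negative")


@dataclass
class LightSchedule:
    """Day-indexed lighting plan.

    Attributes
    ----------
    days : list of (protocol label, list of LightSegment)
        One entry per recording day, in order.
    """

    days: list = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def labels(self) -> list:
        return [label for label, _ in self.days]

    def lux_at(self, zt_abs: float) -> float:
        """Lux at an absolute ZT time (hours since ZT0 of day 0)."""
        day = int(zt_abs // 24.0)
        if day < 0 or day >= self.n_days:
            raise ValueError(f"time {zt_abs} h outside the schedule")
        local = zt_abs - 24.0 * day
        for seg in self.days[day][1]:
            if seg.start_zt <= local < seg.end_zt:
                return seg.lux
        return 0.0

    def lux_array(self, n_bins: int, bin_width_s: float, start_zt_h: float = 0.0) -> np.ndarray:
        """Per-bin lux (evaluated at bin centres) for a uniformly binned recording."""
        t = start_zt_h + (np.arange(n_bins) + 0.5) * bin_width_s / 3600.0
        day = (t // 24.0).astype(int)
        local = t - 24.0 * day
        lux = np.zeros(n_bins)
        for d in range(self.n_days):
            mask = day == d
            if not mask.any():
                continue
            for seg in self.days[d][1]:
                m = mask & (local >= seg.start_zt) & (local < seg.end_zt)
                lux[m] = seg.lux
        if (day >= self.n_days).any():
            raise ValueError("recording extends past the schedule")
        return lux

    def concat(self, other: "LightSchedule") -> "LightSchedule":
        return LightSchedule(days=self.days + other.days)

    def __add__(self, other: "LightSchedule") -> "LightSchedule":
        return self.concat(other)


def make_schedule(protocol: str, n_days: int) -> LightSchedule:
    """Build an ``n_days``-long schedule for one of LD, DLE, LD16_8, DD.

    Schedules concatenate with ``+`` to express protocol switches, e.g.
    ``make_schedule("LD", 7) + make_schedule("DLE", 13)``.
    """
    key = protocol.upper()
    if key not in PROTOCOL_SEGMENTS:
        raise ValueError(
            f"unknown protocol {protocol!r}; expected one of {sorted(PROTOCOL_SEGMENTS)}"
        )
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    segs = [LightSegment(*s) for s in PROTOCOL_SEGMENTS[key]]
    return LightSchedule(days=[(key, segs) for _ in range(n_days)])
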