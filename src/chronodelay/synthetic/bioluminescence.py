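"""Shutter-gated in vivo bioluminescence traces.

Emulates a photomultiplier recording of hepatic luciferase output from a
freely moving mouse: per-minute photon counts, with a programmable shutter
closed for 1 minute in every 15 to sample the background.  Open-shutter
counts are Poisson around ``background(t) + signal(t)``; closed-shutter
counts are Poisson around ``background(t)`` alone.  The background drifts
slowly (linear + slow sinusoid), the signal is a truncated cosine
``A * max(0, 1 + cos(2*pi*(t - phi)/tau))`` peaking at ``phi`` (hours) with
period ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class BioluminescenceParams:
    amplitude: float = 400.0        # peak signal counts/min above background
    background: float = 200.0       # mean background counts/min
    background_drift_per_day: float = -10.0   # linear drift, counts/min/day
    background_wobble: float = 15.0 # amplitude of a slow (50-h) background sinusoid
    shutter_period_min: int = 15    # one closed minute per this many minutes

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.background <= 0:
            raise ValueError("background must be positive")


@dataclass
class BioluminescenceTrace:
    counts: np.ndarray          # per-minute photon counts
    shutter_open: np.ndarray    # bool per minute; False = closed (background)
    start_h: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_minutes(self) -> int:
        return len(self.counts)

    @property
    def times_h(self) -> np.ndarray:
        return self.start_h + (np.arange(self.n_minutes) + 0.5) / 60.0


def generate_bioluminescence(
    phi_true_h: float,
    tau_true_h: float,
    days: int,
    params: BioluminescenceParams | None = None,
    seed: int = 0,
) -> BioluminescenceTrace:
    """Simulate ``days`` of per-minute counts with known acrophase and period."""
    if days < 2:
        raise ValueError("need at least 2 days of recording")
    params = params or BioluminescenceParams()
    n = days * 24 * 60
    t = (np.arange(n) + 0.5) / 60.0  # hours
    bg = (
        params.background
        + params.background_drift_per_day * t / 24.0
        + params.background_wobble * np.sin(2 * np.pi * t / 50.0)
    )
    bg = np.maximum(bg, 1.0)
    signal = params.amplitude * np.maximum(
        0.0, 1.0 + np.cos(2 * np.pi * (t - phi_true_h) / tau_true_h)
    )
    # minute (shutter_period - 1) of each block is closed
    shutter_open = (np.arange(n) % params.shutter_period_min) != params.shutter_period_min - 1
    rate = np.where(shutter_open, bg + signal, bg)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate)
    truth = {
        "phi_h": phi_true_h,
        "tau_h": tau_true_h,
        "params": asdict(params),
    }
    return BioluminescenceTrace(counts=counts, shutter_open=shutter_open, ground_truth=truth)
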