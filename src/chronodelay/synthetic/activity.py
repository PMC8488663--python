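"""Poisson two-state generator for passive-infrared (PIR) activity counts.

The model is deliberately minimal: a nocturnal mouse is "behaviourally active"
inside a daily window and "at rest" outside it, and PIR counts in each 10-s
bin are Poisson with rate ``lambda_active`` (modulated, see below) or
``lambda_rest``.  Everything a phase-marker or sleep pipeline measures depends
only on the geometry of that rate profile, not on richer count statistics.

Phase dynamics
--------------
The active window nominally occupies ZT[12, 12+alpha).  Under a phase-delaying
protocol each marker target is approached geometrically at ``k_reentrain`` per
day (``psi_{d+1} = psi_d + k (psi_target - psi_d)``), i.e. the stored
trajectory equals the closed form ``psi_target * (1 - (1-k)**d)`` with ``d``
days since the protocol switch.  Under constant darkness the window free-runs:
it advances by ``tau_h - 24`` hours per day from its last entrained phase.

Because activity onset, balance-midpoint and offset can delay by *different*
amounts (the window compresses and its mass shifts), three marker targets are
supported: the window start tracks the onset target, the window length absorbs
the onset-offset difference, and a two-level within-window density step places
the 8-h activity-balance midpoint at its own target.

Light masking multiplies the rate by ``masking`` whenever the concurrent lux
is dim, i.e. strictly between 0 and 200 lx (the evening dim-light segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ..schedules import LightSchedule

BIN_S = 10
BINS_PER_DAY = 8640


@dataclass
class ActivityGenParams:
    lambda_active: float = 2.0     # mean counts / 10-s bin while active
    lambda_rest: float = 0.13      # mean counts / 10-s bin during quiet rest
    # brief arousals fragment rest-phase sleep, as in real PIR recordings
    arousal_rate_per_h: float = 0.5
    arousal_duration_h: float = 0.4   # mean (exponential) arousal length
    arousal_lambda: float = 0.7       # counts / 10-s bin during an arousal
    # naps punctuate the active phase, giving realistic dark-phase sleep
    nap_rate_per_h: float = 0.5
    nap_duration_h: float = 0.3       # mean (exponential) nap length
    alpha_h: float = 12.0          # active-period duration under LD, hours
    psi_target_h: float = 0.0      # steady-state onset delay vs ZT12, hours
    psi_midpoint_target_h: Optional[float] = None  # default: mean(onset, offset) targets
    psi_offset_target_h: Optional[float] = None    # default: onset target
    psi_initial_h: float = 0.0     # phase carried into day 0 (prior lighting history)
    k_reentrain: float = 0.3       # per-day fractional approach to the target
    masking: float = 0.8           # rate multiplier in dim-lit (0 < lux < 200) bins
    ultradian_depth: float = 0.0   # in [0, 1]; 0 disables ultradian modulation
    ultradian_period_h: float = 8.0
    tau_h: float = 23.7            # free-running period used under DD
    seed: int = 0

    def __post_init__(self):
        if not self.lambda_active > self.lambda_rest >= 0:
            raise ValueError("need lambda_active > lambda_rest >= 0")
        if not 0 < self.k_reentrain <= 1:
            raise ValueError("k_reentrain must be in (0, 1]")
        if not 0 <= self.masking <= 1:
            raise ValueError("masking must be in [0, 1]")
        if not 0 <= self.ultradian_depth <= 1:
            raise ValueError("ultradian_depth must be in [0, 1]")
        if not 0 < self.alpha_h < 24:
            raise ValueError("alpha_h must be in (0, 24)")

    @property
    def offset_target(self) -> float:
        return self.psi_target_h if self.psi_offset_target_h is None else self.psi_offset_target_h

    @property
    def midpoint_target(self) -> float:
        if self.psi_midpoint_target_h is not None:
            return self.psi_midpoint_target_h
        return 0.5 * (self.psi_target_h + self.offset_target)


@dataclass
class ActivityRecording:
    counts: np.ndarray
    schedule: LightSchedule
    bin_width_s: int = BIN_S
    start_zt_h: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return len(self.counts) // BINS_PER_DAY

    @property
    def times_h(self) -> np.ndarray:
        """Bin-centre times, absolute ZT hours."""
        return self.start_zt_h + (np.arange(len(self.counts)) + 0.5) * self.bin_width_s / 3600.0


def psi_trajectory(labels, params: ActivityGenParams) -> np.ndarray:
    """Per-day phase state ``(onset, midpoint, offset)`` delays, shape (n_days, 3).

    Entrained protocols relax geometrically toward their targets (target 0
    under LD); DD days drift by ``tau_h - 24`` per day from the previous state.
    """
    tgt = np.array([params.psi_target_h, params.midpoint_target, params.offset_target])
    k = params.k_reentrain
    psi = np.empty((len(labels), 3))
    state = np.full(3, params.psi_initial_h, dtype=float)
    for d, label in enumerate(labels):
        if label == "DD":
            # day 0 expresses the carried-in phase; drift starts on day 1
            if d > 0:
                state = state + (params.tau_h - 24.0)
            psi[d] = state
        else:
            target = np.zeros(3) if label == "LD" else tgt
            state = state + k * (target - state)
            psi[d] = state
    return psi


def _window_geometry(psi_row: np.ndarray, alpha_h: float):
    """Active-window (start, length, density median) for one day's delays.

    The onset target fixes the window start, the onset-offset difference the
    window length, and the midpoint target the median ``x_m`` of the
    within-window activity density (which is where the 8-h activity-balance
    rule puts the midpoint for windows shorter than 16 h).
    """
    on, mid, off = psi_row
    start = 12.0 + on
    length = alpha_h + (off - on)
    if length <= 0 or length >= 24:
        raise ValueError("marker targets imply a degenerate active window")
    x_m = (12.0 + alpha_h / 2.0 + mid - start) / length
    x_m = float(min(max(x_m, 0.2), 0.8))
    return start, length, x_m


def _density(x: np.ndarray, x_m: float) -> np.ndarray:
    """Two-level unit-mean density on [0, 1] with median ``x_m``.

    A step density keeps both window edges sharp (a linear tilt starves the
    trailing edge, which breaks the downward moving-average crossing); the
    high level spans 1.5 medians so three quarters of the activity falls
    before/after the step.
    """
    if abs(x_m - 0.5) < 1e-9:
        return np.ones_like(x)
    if x_m < 0.5:
        c = 1.5 * x_m
        h1 = 0.5 / x_m
        h2 = 0.25 / (1.0 - c)
        return np.where(x < c, h1, h2)
    # back-loaded: mirror of the front-loaded case
    return _density(1.0 - x, 1.0 - x_m)


def _arousal_fraction(params: ActivityGenParams) -> float:
    """Stationary fraction of rest time spent in arousal bursts."""
    return min(params.arousal_rate_per_h * params.arousal_duration_h, 0.8)


def _nap_fraction(params: ActivityGenParams) -> float:
    """Stationary fraction of active time spent napping."""
    return min(params.nap_rate_per_h * params.nap_duration_h, 0.8)


def mean_rest_rate(params: ActivityGenParams) -> float:
    """Mean rest-phase rate once arousal bursts are averaged in."""
    f = _arousal_fraction(params)
    return (1.0 - f) * params.lambda_rest + f * params.arousal_lambda


def _segment_mask(rng, n_bins: int, rate_per_h: float, duration_h: float) -> "np.ndarray":
    """Boolean mask of Poisson-arriving segments with exponential durations."""
    mask = np.zeros(n_bins, dtype=bool)
    total_h = n_bins * BIN_S / 3600.0
    n_seg = rng.poisson(rate_per_h * total_h)
    starts = rng.uniform(0.0, total_h, n_seg)
    durs = rng.exponential(duration_h, n_seg)
    for s0, du in zip(starts, durs):
        i0 = int(s0 * 3600 / BIN_S)
        i1 = min(int((s0 + du) * 3600 / BIN_S) + 1, n_bins)
        mask[i0:i1] = True
    return mask


def _build_rate(psi: np.ndarray, params: ActivityGenParams, lux: np.ndarray) -> tuple:
    """Mean rate per 10-s bin and the active-window mask (no noise).

    Rest bins carry the arousal-averaged mean rest rate; the stochastic
    arousal process itself is drawn in :func:`generate_activity`.
    """
    n = len(psi) * BINS_PER_DAY
    t = (np.arange(n) + 0.5) * BIN_S / 3600.0
    rate = np.full(n, mean_rest_rate(params), dtype=float)
    active = np.zeros(n, dtype=bool)
    for d in range(len(psi)):
        start, length, x_m = _window_geometry(psi[d], params.alpha_h)
        a = 24.0 * d + start
        sel = (t >= a) & (t < a + length)
        active |= sel
        x = (t[sel] - a) / length
        f_nap = _nap_fraction(params)
        rate[sel] = ((1.0 - f_nap) * params.lambda_active * _density(x, x_m)
                     + f_nap * params.lambda_rest)
    if params.ultradian_depth > 0:
        mod = 1.0 + params.ultradian_depth * np.cos(2 * np.pi * t / params.ultradian_period_h)
        rate[active] *= mod[active]
    dim = (lux > 0) & (lux < 200)
    rate[dim] *= params.masking
    return rate, active


_CAL_CACHE: dict = {}


def _detected_markers(rate: np.ndarray) -> np.ndarray:
    """Mean steady-state (onset, midpoint, offset) local times on a noiseless rate."""
    from ..activity_phase import SmoothedActivity, daily_onset_offset, daily_midpoint

    sm = SmoothedActivity.from_counts(rate)
    oo = daily_onset_offset(sm, len(rate) // BINS_PER_DAY)
    mid = daily_midpoint(rate)
    core = slice(2, 6)  # interior days, free of moving-average edge loss
    return np.array([
        np.nanmean(oo["onset_zt"].to_numpy()[core]),
        np.nanmean(mid["midpoint_zt"].to_numpy()[core]),
        np.nanmean(oo["offset_zt"].to_numpy()[core]),
    ])


def _steady_state_correction(params: ActivityGenParams, label: str) -> np.ndarray:
    """Window-state adjustment making the crossing/balance detectors recover
    the programmed markers exactly on the noise-free steady-state rate.

    The moving-average crossing rules are biased when the active window's
    duty cycle departs from 50% or its density is tilted, so the programmed
    delay targets are Newton-corrected against the detectors themselves.
    """
    from ..schedules import make_schedule

    tgt = np.array([params.psi_target_h, params.midpoint_target, params.offset_target])
    key = (label, tuple(np.round(tgt, 6)), params.alpha_h, params.masking,
           params.lambda_active, round(mean_rest_rate(params), 9),
           round(_nap_fraction(params), 9),
           params.ultradian_depth, params.ultradian_period_h)
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    n_cal = 8
    lux = make_schedule(label, n_cal).lux_array(n_cal * BINS_PER_DAY, BIN_S)
    expected = tgt + np.array([12.0, 12.0 + params.alpha_h / 2.0, 12.0 + params.alpha_h])
    adj = tgt.copy()
    for _ in range(2):
        rate, _ = _build_rate(np.tile(adj, (n_cal, 1)), params, lux)
        detected = _detected_markers(rate)
        if not np.all(np.isfinite(detected)):
            break
        adj = adj - (detected - expected)
    _CAL_CACHE[key] = adj - tgt
    return _CAL_CACHE[key]


def rate_profile(params: ActivityGenParams, schedule: LightSchedule) -> tuple:
    """Noise-free Poisson rate per 10-s bin, plus the ground-truth dictionary."""
    n_days = schedule.n_days
    n = n_days * BINS_PER_DAY
    psi = psi_trajectory(schedule.labels, params)

    # detector-calibrated window states: the correction scales with how far
    # re-entrainment has progressed, and is zero under LD/DD (50% duty cycle)
    psi_adj = psi.copy()
    tgt_on = params.psi_target_h
    if tgt_on != 0.0:
        for label in set(schedule.labels) - {"LD", "DD"}:
            corr = _steady_state_correction(params, label)
            for d, lab in enumerate(schedule.labels):
                if lab == label:
                    w = psi[d, 0] / tgt_on
                    psi_adj[d] = psi[d] + w * corr

    lux = schedule.lux_array(n, BIN_S)
    rate, active = _build_rate(psi_adj, params, lux)

    onsets, offsets = [], []
    for d in range(n_days):
        start, length, _ = _window_geometry(psi[d], params.alpha_h)
        onsets.append(24.0 * d + start)
        offsets.append(24.0 * d + start + length)
    truth = {
        "psi_d": psi,
        "onset_h": np.array(onsets),
        "offset_h": np.array(offsets),
        "active_mask": active,
        "dim_mask": (lux > 0) & (lux < 200),
        "params": asdict(params),
    }
    return rate, truth


def generate_activity(
    params: ActivityGenParams,
    schedule: LightSchedule,
    seed: Optional[int] = None,
) -> ActivityRecording:
    """Draw a PIR recording (10-s Poisson counts) from the two-state model.

    Rest-phase bins alternate between quiet rest (``lambda_rest``) and brief
    arousal bursts (``arousal_lambda``, Poisson-arriving with exponential
    durations), fragmenting immobility-defined sleep the way spontaneous
    arousals do in real recordings; the mean rest rate matches the
    calibrated profile from :func:`rate_profile`.
    """
    rate, truth = rate_profile(params, schedule)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rate = rate.copy()
    n = len(rate)
    active = truth["active_mask"]
    dim = truth["dim_mask"]
    maskfac = np.where(dim, params.masking, 1.0)
    f_a = _arousal_fraction(params)
    if f_a > 0:
        burst = _segment_mask(rng, n, params.arousal_rate_per_h, params.arousal_duration_h)
        rest = ~active
        rate[rest & burst] = params.arousal_lambda
        rate[rest & ~burst] = params.lambda_rest
        rate[rest & dim] *= params.masking
    f_n = _nap_fraction(params)
    if f_n > 0:
        nap = _segment_mask(rng, n, params.nap_rate_per_h, params.nap_duration_h)
        # recover the non-nap rate from the stored mean so means stay calibrated
        non_nap = (rate - f_n * params.lambda_rest * maskfac) / (1.0 - f_n)
        sel = active & nap
        rate[sel] = params.lambda_rest * maskfac[sel]
        sel = active & ~nap
        rate[sel] = non_nap[sel]
    counts = rng.poisson(rate)
    return ActivityRecording(counts=counts, schedule=schedule, ground_truth=truth)
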