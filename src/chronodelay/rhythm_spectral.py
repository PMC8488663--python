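"""Bioluminescence rhythm analysis and wavelet power spectra.

Pipeline for shutter-gated photomultiplier traces: subtract a background
linearly interpolated between the closed-shutter minutes, block-average to
15-min resolution, isolate the circadian (16-32 h) band with a discrete
wavelet transform, then estimate acrophase, period and signal-to-noise
ratio from the band-limited signal.  A continuous wavelet transform of
activity yields the period-resolved power used to compare circadian (~24 h)
and ultradian (~8 h) components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats

CIRCADIAN_BAND_H = (16.0, 32.0)
NOISE_BAND_MAX_H = 4.0
DWT_WAVELET = "sym4"  # least-asymmetric orthogonal family
ANALYSIS_DT_H = 0.25  # 15-min block averages stabilise Poisson noise


@dataclass
class CorrectedTrace:
    corrected: np.ndarray   # per-minute background-corrected counts
    background: np.ndarray
    open_mask: np.ndarray
    start_h: float = 0.0


@dataclass
class RhythmEstimate:
    phi_h: float            # circular acrophase in [0, 24)
    tau_h: float
    snr: float
    cycle_peaks_h: np.ndarray = field(default_factory=lambda: np.empty(0))


def background_correct(trace) -> CorrectedTrace:
    """Remove the interpolated closed-shutter background from a trace.

    The background is linearly interpolated between closed-shutter minutes
    (exact for piecewise-linear drift); corrected values at closed minutes
    are themselves interpolated from the neighbouring open minutes.
    """
    counts = np.asarray(trace.counts, dtype=float)
    open_mask = np.asarray(trace.shutter_open, dtype=bool)
    closed = np.flatnonzero(~open_mask)
    if len(closed) == 0:
        raise ValueError("trace has no closed-shutter minutes to sample background")
    idx = np.arange(len(counts))
    background = np.interp(idx, closed, counts[closed])
    if len(closed) >= 2:
        # linear extrapolation outside the first/last closed minute keeps the
        # correction exact for linear drift over the whole trace
        s0 = (counts[closed[1]] - counts[closed[0]]) / (closed[1] - closed[0])
        background[:closed[0]] = counts[closed[0]] + s0 * (idx[:closed[0]] - closed[0])
        s1 = (counts[closed[-1]] - counts[closed[-2]]) / (closed[-1] - closed[-2])
        background[closed[-1]:] = counts[closed[-1]] + s1 * (idx[closed[-1]:] - closed[-1])
    corrected = counts - background
    opens = np.flatnonzero(open_mask)
    corrected[closed] = np.interp(closed, opens, corrected[opens])
    return CorrectedTrace(corrected=corrected, background=background,
                          open_mask=open_mask, start_h=getattr(trace, "start_h", 0.0))


def block_average(x: np.ndarray, block: int) -> np.ndarray:
    n = (len(x) // block) * block
    return np.asarray(x[:n], dtype=float).reshape(-1, block).mean(axis=1)


def _band_levels(dt_h: float, band) -> list:
    """DWT detail levels whose dyadic pass-band [2^l, 2^(l+1)] * dt lies in band."""
    levels = []
    level = 1
    while 2 ** level * dt_h < band[1] * 1.001:
        lo, hi = 2 ** level * dt_h, 2 ** (level + 1) * dt_h
        if lo >= band[0] * 0.999 and hi <= band[1] * 1.001:
            levels.append(level)
        level += 1
    return levels


def dwt_band(x: np.ndarray, dt_h: float, band=CIRCADIAN_BAND_H,
             wavelet: str = DWT_WAVELET) -> np.ndarray:
    """Reconstruction of x from the wavelet detail levels covering ``band``.

    Uses the stationary (undecimated) wavelet transform: the decimated
    transform's detail reconstructions are shift-variant and displace peak
    times by up to hours, which is fatal for acrophase work.  Levels outside
    the band (trend above, noise below) are zeroed before inversion;
    reflection padding at the end handles non-dyadic lengths.
    """
    levels = _band_levels(dt_h, band)
    if not levels:
        raise ValueError(f"band {band} h not resolvable at dt = {dt_h} h")
    max_needed = max(levels)
    if len(x) < 2 ** max_needed:
        raise ValueError(
            f"trace too short: need >= {2 ** max_needed} samples "
            f"({2 ** max_needed * dt_h:.0f} h at dt = {dt_h} h) for the {band} h band"
        )
    n = len(x)
    # remove the linear trend first: at circadian band depths the wavelet
    # filters span most of a several-day trace, so the reflection kink of a
    # residual trend would otherwise leak into the band
    x = sps.detrend(np.asarray(x, dtype=float), type="linear")
    pad = (-n) % (2 ** max_needed)
    xp = np.pad(x, (0, pad), mode="reflect")
    coeffs = pywt.swt(xp, wavelet, level=max_needed)
    # coeffs = [(cA_L, cD_L), ..., (cA_1, cD_1)]
    kept = []
    for i, (ca, cd) in enumerate(coeffs):
        level = max_needed - i
        kept.append((np.zeros_like(ca), cd if level in levels else np.zeros_like(cd)))
    return pywt.iswt(kept, wavelet)[:n]


def dwt_detrend(corrected: CorrectedTrace, dt_h: float = ANALYSIS_DT_H) -> np.ndarray:
    """Circadian-band (16-32 h) component of a corrected trace at 15-min steps."""
    block = int(round(dt_h * 60))
    x = block_average(corrected.corrected, block)
    return dwt_band(x, dt_h)


def snr(corrected: CorrectedTrace, dt_h: float = ANALYSIS_DT_H) -> float:
    """Variance ratio of the circadian band to the sub-4-h noise band."""
    block = int(round(dt_h * 60))
    x = block_average(corrected.corrected, block)
    circ = dwt_band(x, dt_h, CIRCADIAN_BAND_H)
    noise = dwt_band(x, dt_h, (2 * dt_h, NOISE_BAND_MAX_H))
    nv = float(np.var(noise))
    if nv == 0.0:
        return float("inf")
    return float(np.var(circ) / nv)


def _refine_peak(y: np.ndarray, i: int) -> float:
    """Parabolic sub-sample refinement of a local maximum index."""
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom != 0:
            return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i)


def cycle_peaks(series: np.ndarray, dt_h: float = ANALYSIS_DT_H,
                assumed_period_h: float = 24.0, start_h: float = 0.0,
                edge_margin_h: float = 4.0) -> np.ndarray:
    """Times (hours) of successive cycle peaks of a band-limited series.

    Peaks with non-positive amplitude and peaks within ``edge_margin_h`` of
    either trace end (wavelet boundary artefacts) are discarded.
    """
    dist = max(1, int(0.7 * assumed_period_h / dt_h))
    idx, _ = sps.find_peaks(series, distance=dist)
    idx = idx[series[idx] > 0]
    margin = edge_margin_h / dt_h
    idx = idx[(idx >= margin) & (idx <= len(series) - 1 - margin)]
    return np.array([start_h + (_refine_peak(series, i) + 0.5) * dt_h for i in idx])


def circular_mean_h(hours, period: float = 24.0) -> float:
    ang = 2 * np.pi * np.asarray(hours, dtype=float) / period
    m = np.angle(np.mean(np.exp(1j * ang)))
    return float((m * period / (2 * np.pi)) % period)


def wrap_diff_h(a: float, b: float, period: float = 24.0) -> float:
    """a - b wrapped into (-period/2, period/2]."""
    d = (a - b) % period
    if d > period / 2:
        d -= period
    return float(d)


def acrophase(series: np.ndarray, dt_h: float = ANALYSIS_DT_H,
              assumed_period_h: float = 24.0, start_h: float = 0.0) -> RhythmEstimate:
    """Circular-mean acrophase of per-cycle peaks of a band-limited series."""
    peaks = cycle_peaks(series, dt_h, assumed_period_h, start_h)
    if len(peaks) < 2:
        warnings.warn("fewer than 2 cycle peaks; acrophase undefined")
        return RhythmEstimate(phi_h=float("nan"), tau_h=float("nan"), snr=float("nan"))
    phi = circular_mean_h(peaks % 24.0)
    tau = estimate_period(peaks)
    return RhythmEstimate(phi_h=phi, tau_h=tau, snr=float("nan"), cycle_peaks_h=peaks)


def estimate_period(peaks_h: np.ndarray) -> float:
    """Period from the drift of per-cycle acrophases: 24 + slope vs cycle index.

    The first and last cycle are dropped when five or more peaks are
    available: band-filter edge effects pull boundary peaks inward, which
    otherwise biases the slope.
    """
    peaks_h = np.asarray(peaks_h, dtype=float)
    if len(peaks_h) < 3:
        return float("nan")
    if len(peaks_h) >= 5:
        peaks_h = peaks_h[1:-1]
    k = np.arange(len(peaks_h))
    acro = peaks_h - 24.0 * k
    slope = stats.linregress(k, acro).slope
    return 24.0 + float(slope)


def analyze_trace(trace, assumed_period_h: float = 24.0) -> RhythmEstimate:
    """Full pipeline: background correction, DWT band isolation, phi/tau/SNR."""
    corr = background_correct(trace)
    circ = dwt_detrend(corr)
    est = acrophase(circ, ANALYSIS_DT_H, assumed_period_h, corr.start_h)
    return RhythmEstimate(phi_h=est.phi_h, tau_h=est.tau_h,
                          snr=snr(corr), cycle_peaks_h=est.cycle_peaks_h)


@dataclass
class WaveletPowerSpectrum:
    period_h: np.ndarray
    power: np.ndarray

    def power_at(self, period_h: float) -> float:
        return float(np.interp(period_h, self.period_h, self.power))


def cwt_power(recording, period_grid_h=None, rebin_s: int = 360,
              wavelet: str = "cmor1.5-1.0") -> WaveletPowerSpectrum:
    """Time-averaged continuous-wavelet power of activity per period.

    Activity is rebinned (default 6-min), demeaned and transformed with an
    analytic Morlet wavelet; power at each period is averaged over time with
    a one-period cone-of-influence margin excluded at both edges.
    """
    if period_grid_h is None:
        period_grid_h = np.geomspace(4.0, 32.0, 60)
    period_grid_h = np.asarray(period_grid_h, dtype=float)
    counts = np.asarray(recording.counts, dtype=float)
    block = int(round(rebin_s / recording.bin_width_s))
    x = block_average(counts, block)
    dt_h = rebin_s / 3600.0
    if len(x) * dt_h < 4 * 24:
        raise ValueError("need at least 4 days of activity for the CWT spectrum")
    max_period = len(x) * dt_h / 3.0
    grid = period_grid_h[period_grid_h <= max_period]
    if len(grid) < len(period_grid_h):
        warnings.warn("period grid clipped to the resolvable range")
    fc = pywt.central_frequency(wavelet)
    scales = fc * grid / dt_h
    coef, _ = pywt.cwt(x - x.mean(), scales, wavelet, sampling_period=dt_h)
    power = np.empty(len(grid))
    n = len(x)
    for i, p in enumerate(grid):
        margin = min(int(np.ceil(p / dt_h)), (n - 1) // 2)
        # scale-normalised (bias-corrected) power: white noise is flat in
        # period, so peaks are comparable across the period axis
        power[i] = float(np.mean(np.abs(coef[i, margin:n - margin]) ** 2) / scales[i])
    return WaveletPowerSpectrum(period_h=grid, power=power)
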