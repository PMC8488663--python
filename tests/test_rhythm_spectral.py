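import numpy as np
import pytest

from chronodelay import rhythm_spectral as rs
from chronodelay.schedules import make_schedule
from chronodelay.synthetic import generate_activity, generate_bioluminescence, presets
from chronodelay.synthetic.bioluminescence import BioluminescenceParams, BioluminescenceTrace


def _noiseless_trace(signal_fn, days=5, background_fn=lambda t: 200.0):
    n = days * 1440
    t = (np.arange(n) + 0.5) / 60.0
    shutter_open = (np.arange(n) % 15) != 14
    bg = np.array([background_fn(x) for x in t])
    counts = np.where(shutter_open, bg + signal_fn(t), bg)
    return BioluminescenceTrace(counts=counts, shutter_open=shutter_open)


# ---------------------------------------------------------- background_correct

def test_background_correction_is_exact_for_linear_drift():
    tr = _noiseless_trace(lambda t: 0.0, background_fn=lambda t: 300.0 - 0.5 * t)
    corr = rs.background_correct(tr)
    assert np.allclose(corr.corrected, 0.0, atol=1e-9)


def test_background_correction_noisy_zero_signal_near_zero():
    tr = generate_bioluminescence(6.0, 24.0, 3,
                                  BioluminescenceParams(amplitude=0.0), seed=0)
    corr = rs.background_correct(tr)
    # the interpolated background (1 sample / 15 min) dominates the error
    n_closed = (~tr.shutter_open).sum()
    se = np.sqrt(200.0 / n_closed)
    assert abs(corr.corrected.mean()) < 3 * se


def test_background_correction_recovers_signal_shape():
    sig = lambda t: 100.0 * np.maximum(0.0, 1.0 + np.cos(2 * np.pi * (t - 6) / 24))
    with_bg = _noiseless_trace(sig, background_fn=lambda t: 250.0 + 0.3 * t)
    no_bg = _noiseless_trace(sig, background_fn=lambda t: 0.0)
    a = rs.background_correct(with_bg).corrected
    b = rs.background_correct(no_bg).corrected
    # outside the first/last shutter block (flat extrapolation) they agree
    assert np.allclose(a[15:-15], b[15:-15], atol=1e-6)


def test_background_correct_requires_closed_minutes():
    tr = BioluminescenceTrace(counts=np.ones(100), shutter_open=np.ones(100, bool))
    with pytest.raises(ValueError, match="closed-shutter"):
        rs.background_correct(tr)


# ----------------------------------------------------------------- band filter

def test_band_passes_24h_and_rejects_1h():
    t = np.arange(480) * 0.25
    pure = np.cos(2 * np.pi * (t - 6) / 24.0)
    band = rs.dwt_band(pure, 0.25)
    core = slice(40, 440)
    assert np.corrcoef(pure[core], band[core])[0, 1] > 0.99
    fast = np.cos(2 * np.pi * t / 1.0)
    assert rs.dwt_band(fast, 0.25).std() < 0.05 * fast.std()


def test_band_removes_linear_trend():
    t = np.arange(480) * 0.25
    trend = 0.05 * t            # range 6 over the trace
    sig = np.cos(2 * np.pi * t / 24.0)
    band = rs.dwt_band(sig + trend, 0.25)
    band_sig = rs.dwt_band(sig, 0.25)
    core = slice(40, 440)
    assert np.max(np.abs(band[core] - band_sig[core])) < 0.05 * np.ptp(trend)


def test_band_too_short_trace_rejected():
    with pytest.raises(ValueError, match="trace too short"):
        rs.dwt_band(np.ones(32), 0.25)


# ------------------------------------------------------------- acrophase / tau

def test_acrophase_recovery_and_time_shift_equivariance():
    tr = generate_bioluminescence(6.0, 24.0, 5, seed=1)
    est = rs.analyze_trace(tr)
    assert est.phi_h == pytest.approx(6.0, abs=0.25)
    shifted = BioluminescenceTrace(counts=tr.counts, shutter_open=tr.shutter_open,
                                   start_h=3.0)
    est3 = rs.analyze_trace(shifted)
    assert rs.wrap_diff_h(est3.phi_h, est.phi_h) == pytest.approx(3.0, abs=0.02)


def test_parameter_recovery_over_seeds():
    """phi within 0.25 h and tau within 0.15 h at the default preset."""
    phi_err, tau_err = [], []
    for seed in range(20):
        tr = generate_bioluminescence(6.0, 24.0, 5, seed=200 + seed)
        est = rs.analyze_trace(tr)
        phi_err.append(rs.wrap_diff_h(est.phi_h, 6.0))
        tau_err.append(est.tau_h - 24.0)
    assert np.max(np.abs(phi_err)) < 0.25
    assert np.max(np.abs(tau_err)) < 0.15


def test_period_estimation_shorter_than_24h():
    taus = [rs.analyze_trace(generate_bioluminescence(8.0, 23.5, 5, seed=90 + i)).tau_h
            for i in range(6)]
    assert np.mean(taus) == pytest.approx(23.5, abs=0.15)


def test_period_invariant_to_amplitude_scaling():
    t = np.arange(480) * 0.25
    sig = np.cos(2 * np.pi * t / 23.5)
    p1 = rs.estimate_period(rs.cycle_peaks(rs.dwt_band(sig, 0.25)))
    p2 = rs.estimate_period(rs.cycle_peaks(rs.dwt_band(100 * sig, 0.25)))
    assert p1 == pytest.approx(p2, abs=1e-9)


def test_estimate_period_needs_three_peaks():
    assert np.isnan(rs.estimate_period(np.array([6.0, 30.0])))


# ------------------------------------------------------------------------- SNR

def test_snr_strong_rhythm_vs_pure_noise():
    strong = generate_bioluminescence(6.0, 24.0, 5, seed=3)
    assert rs.snr(rs.background_correct(strong)) > 10
    flat = generate_bioluminescence(6.0, 24.0, 5,
                                    BioluminescenceParams(amplitude=0.0), seed=3)
    assert rs.snr(rs.background_correct(flat)) < 1.5


def test_snr_quadruples_when_amplitude_doubles():
    # fixed noise floor: variance scaling is exact only when the noise does
    # not grow with the signal (Poisson shot noise does)
    rng = np.random.default_rng(4)
    noise = rng.normal(0.0, 20.0, 5 * 1440)
    shutter_open = (np.arange(5 * 1440) % 15) != 14

    def snr_at(amp):
        t = (np.arange(5 * 1440) + 0.5) / 60.0
        sig = amp * np.maximum(0.0, 1.0 + np.cos(2 * np.pi * (t - 6) / 24))
        counts = 200.0 + np.where(shutter_open, sig, 0.0) + noise
        tr = BioluminescenceTrace(counts=counts, shutter_open=shutter_open)
        return rs.snr(rs.background_correct(tr))

    assert snr_at(400.0) / snr_at(200.0) == pytest.approx(4.0, rel=0.2)


# ------------------------------------------------------------------------- CWT

def test_cwt_peak_at_24h_for_square_wave_activity():
    params = presets.activity_params("dd_prior_ld", psi_target_h=0.0, tau_h=24.0,
                                     arousal_rate_per_h=0.0, nap_rate_per_h=0.0)
    rec = generate_activity(params, make_schedule("LD", 6), seed=6)
    sp = rs.cwt_power(rec)
    assert 22 <= sp.period_h[np.argmax(sp.power)] <= 26


def test_cwt_ultradian_power_rises_under_dim_evening_light():
    """The shortened, fragmented night raises ~8-h power relative to LD."""
    ld = generate_activity(
        presets.activity_params("dd_prior_ld", psi_target_h=0.0, tau_h=24.0),
        make_schedule("LD", 7), seed=11)
    dle = generate_activity(presets.activity_params("wt_dle", ultradian_depth=0.35),
                            make_schedule("DLE", 7), seed=11)
    ratio = rs.cwt_power(dle).power_at(8) / rs.cwt_power(ld).power_at(8)
    assert ratio > 1.0
    # ~24-h power remains dominant under DLE
    assert rs.cwt_power(dle).power_at(24) > 3 * rs.cwt_power(dle).power_at(8)


def test_cwt_white_noise_has_no_dominant_period():
    class Rec:
        counts = np.random.default_rng(0).poisson(1.0, 6 * 8640)
        bin_width_s = 10
    sp = rs.cwt_power(Rec())
    assert sp.power.max() < 3 * np.median(sp.power)


def test_cwt_grid_clipped_with_warning():
    class Rec:
        counts = np.random.default_rng(1).poisson(1.0, 4 * 8640)
        bin_width_s = 10
    with pytest.warns(UserWarning, match="clipped"):
        sp = rs.cwt_power(Rec(), period_grid_h=np.array([8.0, 24.0, 48.0]))
    assert sp.period_h.max() <= 32.0
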