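import numpy as np
import pandas as pd
import pytest

from chronodelay import activity_phase as ap
from chronodelay.schedules import make_schedule
from chronodelay.synthetic import ActivityGenParams, generate_activity
from chronodelay.synthetic.activity import rate_profile


# ---------------------------------------------------------------- moving_average

def test_moving_average_constant_series():
    out = ap.moving_average(np.full(50, 3.7), 7)
    assert np.allclose(out[3:-3], 3.7)
    assert np.isnan(out[:3]).all() and np.isnan(out[-3:]).all()


def test_moving_average_small_example():
    out = ap.moving_average([0, 0, 6, 0, 0], 3)
    assert np.isnan(out[0]) and np.isnan(out[-1])
    assert np.allclose(out[1:4], [2, 2, 2])


def test_moving_average_impulse_response_plateau():
    x = np.zeros(21)
    x[10] = 1.0
    out = ap.moving_average(x, 5)
    assert np.allclose(out[8:13], 0.2)
    assert np.allclose(out[2:8], 0.0) and np.allclose(out[13:19], 0.0)


def test_moving_average_even_window_widened_to_odd():
    # 4 -> 5: symmetric straddle, mean of 5 bins
    out = ap.moving_average(np.arange(10, dtype=float), 4)
    assert np.allclose(out[2:-2], np.arange(2, 8))


def test_moving_average_window_longer_than_series_warns_all_nan():
    with pytest.warns(UserWarning, match="longer than series"):
        out = ap.moving_average([1.0, 2.0], 9)
    assert np.isnan(out).all()


def test_moving_average_rejects_bad_window():
    with pytest.raises(ValueError):
        ap.moving_average([1.0], 0)


# ------------------------------------------------------------------- crossings

@pytest.mark.parametrize("delta, expected", [
    ([-1, 1], [(1, 1)]),
    ([2, 2, 2], []),
    ([-3, -1, -2], []),
    ([2, -1, -1, 3], [(1, -1), (3, 1)]),
])
def test_crossing_sign_rules(delta, expected):
    assert ap.crossings(delta) == expected


def test_crossing_through_exact_zero_run():
    # the crossing registers at the first nonzero bin of opposite sign
    assert ap.crossings([1.0, 0.0, 0.0, -2.0]) == [(3, -1)]
    assert ap.crossings([-1.0, 0.0, 3.0]) == [(2, 1)]
    # zeros without a sign change register nothing
    assert ap.crossings([1.0, 0.0, 2.0]) == []


# ------------------------------------------------- brute-force oracle equivalence

def _oracle_markers(counts, n_days):
    """Literal re-implementation: direct centred means, explicit sign products."""
    x = np.asarray(counts, dtype=float)
    n = len(x)

    def centred_ma(series, w):
        if w % 2 == 0:
            w += 1
        h = w // 2
        out = np.full(n, np.nan)
        for i in range(h, n - h):
            win = series[i - h:i + h + 1]
            if np.isfinite(win).all():
                out[i] = win.mean()
        return out

    base = centred_ma(x, 360)
    short = centred_ma(base, 1080)
    long_ = centred_ma(base, 8640)
    delta = short - long_

    ups, downs = [], []
    last_sign = 0
    for i in range(n):
        d = delta[i]
        if not np.isfinite(d) or d == 0:
            continue
        s = 1 if d > 0 else -1
        if last_sign != 0 and s != last_sign:
            (ups if s > 0 else downs).append(i)
        last_sign = s

    rows = []
    for day in range(n_days):
        i0 = int((24 * day + 6) * 360)
        i1 = int((24 * day + 30) * 360)
        if i0 < 0 or i1 > n or not (np.isfinite(delta[i0]) and np.isfinite(delta[i1 - 1])):
            rows.append((day, np.nan, np.nan))
            continue
        day_ups = [i for i in ups if i0 <= i < i1]
        onset_i = day_ups[0] if day_ups else None
        onset = (onset_i + 0.5) / 360.0 - 24 * day if onset_i is not None else np.nan
        offset = np.nan
        if onset_i is not None:
            day_downs = [i for i in downs if onset_i < i < i1]
            if day_downs:
                offset = (day_downs[-1] + 0.5) / 360.0 - 24 * day
        rows.append((day, onset, offset))
    return pd.DataFrame(rows, columns=["day", "onset_zt", "offset_zt"])


def test_onset_offset_matches_brute_force_oracle_on_two_day_series():
    """Pipeline and literal bin-by-bin scan agree exactly on short noisy series."""
    rng = np.random.default_rng(3)
    t = (np.arange(2 * 8640) + 0.5) / 360.0
    rate = np.where((t % 24) >= 12, 2.0, 0.2)
    counts = rng.poisson(rate)
    sm = ap.SmoothedActivity.from_counts(counts)
    got = ap.daily_onset_offset(sm, 2)
    want = _oracle_markers(counts, 2)
    pd.testing.assert_frame_equal(got, want)


def test_constant_activity_has_no_markers():
    sm = ap.SmoothedActivity.from_counts(np.full(2 * 8640, 5.0))
    tab = ap.daily_onset_offset(sm, 2)
    assert tab[["onset_zt", "offset_zt"]].isna().all().all()


# -------------------------------------------------------------------- midpoints

def test_midpoint_of_symmetric_block():
    t = (np.arange(3 * 8640) + 0.5) / 360.0
    rate = np.where(np.abs(((t - 18) % 24 + 12) % 24 - 12) < 3, 2.0, 0.0)
    tab = ap.daily_midpoint(rate)
    assert tab.loc[1, "midpoint_zt"] == pytest.approx(18.0, abs=0.05)


def test_midpoint_of_shifted_block():
    # block on ZT[15.6, 27.6): midpoint at its centre 21.6
    t = (np.arange(3 * 8640) + 0.5) / 360.0
    rate = np.where(((t - 15.6) % 24) < 12, 2.0, 0.0)
    tab = ap.daily_midpoint(rate)
    assert tab.loc[1, "midpoint_zt"] == pytest.approx(21.6, abs=0.05)


def test_midpoint_undefined_for_all_zero_counts():
    tab = ap.daily_midpoint(np.zeros(2 * 8640))
    assert tab["midpoint_zt"].isna().all()


# ------------------------------------------------------------------- invariants

@pytest.fixture(scope="module")
def noiseless_two_day_rate():
    params = ActivityGenParams(arousal_rate_per_h=0.0, nap_rate_per_h=0.0)
    rate, _ = rate_profile(params, make_schedule("LD", 3))
    return rate


def test_time_shift_equivariance(noiseless_two_day_rate):
    """Shifting the series by m bins shifts every marker by m bins exactly."""
    m = 73
    shifted = np.roll(noiseless_two_day_rate, m)
    base = ap.daily_onset_offset(ap.SmoothedActivity.from_counts(noiseless_two_day_rate), 3)
    got = ap.daily_onset_offset(ap.SmoothedActivity.from_counts(shifted), 3)
    dt = m * 10 / 3600.0
    assert got.loc[1, "onset_zt"] == pytest.approx(base.loc[1, "onset_zt"] + dt, abs=1e-9)
    assert got.loc[1, "offset_zt"] == pytest.approx(base.loc[1, "offset_zt"] + dt, abs=1e-9)


def test_count_scale_invariance(noiseless_two_day_rate):
    # x4 is exactly representable, so even exact-zero tie-breaks are preserved
    base = ap.daily_onset_offset(ap.SmoothedActivity.from_counts(noiseless_two_day_rate), 3)
    scaled = ap.daily_onset_offset(
        ap.SmoothedActivity.from_counts(noiseless_two_day_rate * 4.0), 3)
    pd.testing.assert_frame_equal(base, scaled)
    mid_a = ap.daily_midpoint(noiseless_two_day_rate)
    mid_b = ap.daily_midpoint(noiseless_two_day_rate * 4.0)
    pd.testing.assert_frame_equal(mid_a, mid_b)


def test_onset_offset_alternation(wt_cohort12):
    """Between consecutive onsets at least one offset is reported."""
    for tab in wt_cohort12["tables"].values():
        sub = tab.dropna(subset=["onset_zt", "offset_zt"])
        # within each day the offset follows the onset on the unwrapped axis
        assert (sub["offset_zt"] > sub["onset_zt"]).all()


# ------------------------------------------------------------------ phase_delay

def test_phase_delay_identical_day_sets_is_zero(wt_cohort12):
    est = ap.phase_delay(wt_cohort12["tables"], "onset", range(1, 6), range(1, 6))
    assert est.mean_h == pytest.approx(0.0, abs=1e-12)


def test_phase_advance_yields_negative_delay():
    params = ActivityGenParams(psi_target_h=-1.0)
    sched = make_schedule("LD", 7) + make_schedule("DLE", 13)
    tables = {f"a{i}": ap.phase_marker_table(generate_activity(params, sched, seed=50 + i))
              for i in range(3)}
    est = ap.phase_delay(tables, "onset", range(0, 7), range(14, 19))
    assert est.mean_h < -0.5


def test_phase_delay_requires_nonempty_day_sets(wt_cohort12):
    with pytest.raises(ValueError):
        ap.phase_delay(wt_cohort12["tables"], "onset", [], range(14, 19))


# -------------------------------------------------------------- free_run_period

def test_free_run_period_from_constructed_onsets():
    entrained = pd.DataFrame({"day": range(6), "onset_zt": [12.1] * 6})
    assert ap.free_run_period(entrained) == pytest.approx(24.0)
    drifting = pd.DataFrame({"day": range(6),
                             "onset_zt": 12.0 + 0.5 * np.arange(6)})
    assert ap.free_run_period(drifting) == pytest.approx(24.5)


def test_free_run_period_needs_four_onsets():
    short = pd.DataFrame({"day": range(6),
                          "onset_zt": [12.0, 12.3, np.nan] + [np.nan] * 3})
    with pytest.warns(UserWarning, match="fewer than 4"):
        assert np.isnan(ap.free_run_period(short))


def test_unwrap_keeps_successive_values_close():
    vals = [23.5, 0.5, 1.5, np.nan, 2.5]
    out = ap.unwrap_markers(vals)
    assert out[1] == pytest.approx(24.5)
    assert out[4] == pytest.approx(26.5)
    assert np.isnan(out[3])
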