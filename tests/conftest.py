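"""Shared fixtures: expensive simulated cohorts are session-scoped."""

import numpy as np
import pytest

from chronodelay import activity_phase as ap
from chronodelay.schedules import make_schedule
from chronodelay.sleep_scoring import score_sleep
from chronodelay.synthetic import generate_activity, presets
from chronodelay.synthetic.recognition import generate_recognition


@pytest.fixture(scope="session")
def wt_cohort12():
    """12 wild-type animals, 7 d LD + 13 d dim-evening-light, fixed seeds."""
    params = presets.activity_params("wt_dle")
    schedule = presets.study_schedule("wt_dle")
    recordings = {}
    tables = {}
    for i in range(12):
        rec = generate_activity(params, schedule, seed=100 + i)
        recordings[f"a{i:02d}"] = rec
        tables[f"a{i:02d}"] = ap.phase_marker_table(rec)
    return {"recordings": recordings, "tables": tables,
            "baseline_days": range(0, 7), "steady_days": range(14, 19)}


@pytest.fixture(scope="session")
def memory_bundle():
    """11 mice with the calibrated sleep-memory coupling preset (fixed seed)."""
    params = presets.activity_params("wt_dle")
    schedule = make_schedule("LD", 7) + make_schedule("DLE", 13)
    recordings = {f"m{i:02d}": generate_activity(params, schedule, seed=7000 + i)
                  for i in range(11)}
    sleep = {m: score_sleep(r) for m, r in recordings.items()}
    dataset = generate_recognition(recordings, presets.memory_calibrated_params(), seed=11)
    return {"recordings": recordings, "sleep": sleep, "dataset": dataset}


def lmm_loglik_oracle(beta, sigma_b2, sigma_e2, X, y, groups):
    """Independent random-intercept Gaussian log-likelihood (direct MVN form)."""
    ll = 0.0
    for gi in np.unique(groups):
        m = groups == gi
        r = y[m] - X[m] @ np.asarray(beta)
        n = int(m.sum())
        V = sigma_e2 * np.eye(n) + sigma_b2 * np.ones((n, n))
        _, logdet = np.linalg.slogdet(V)
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    return float(ll)
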