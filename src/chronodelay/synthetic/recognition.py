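"""Recognition-memory trials coupled to prior sleep history.

Each mouse runs 8 spontaneous-recognition trials (2 lighting conditions x
2 Zeitgeber times x 2 stimulus modalities).  The test-phase recognition
ratio (novel / (novel + familiar) exploration, first 60 s) is linearly
coupled to the mouse's *true* sleep proportion in the 2 h preceding the
trial -- computed by the immobility sleep scorer on the mouse's own
generated PIR counts -- plus a per-mouse random intercept and residual
noise, clamped to [0, 1]:

    r_ij = clamp(beta0 + beta1 * S2h_ij + b_i + e_ij, 0, 1)

Exploration times are back-filled from the ratio given a drawn total
exploration time (log-normal, median ~20 s in the first test minute).
Sample-phase exploration is drawn independently of sleep, so exploration
analyses are null by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..sleep_scoring import score_sleep, prior_sleep
from .activity import ActivityGenParams, ActivityRecording, generate_activity
from ..schedules import make_schedule

# (condition, trial day, trial-start ZT, stimulus).  LD trials run late in the
# baseline week; DLE trials run after re-entrainment is essentially complete.
TRIAL_SCHEDULE = [
    ("LD", 3, 2.0, "object"),
    ("LD", 4, 14.0, "object"),
    ("LD", 5, 2.0, "odor"),
    ("LD", 6, 14.0, "odor"),
    ("DLE", 16, 2.0, "object"),
    ("DLE", 17, 14.0, "object"),
    ("DLE", 18, 2.0, "odor"),
    ("DLE", 19, 14.0, "odor"),
]

SEGMENTS = ((0, 60), (60, 120), (120, 180))


@dataclass
class RecognitionGenParams:
    beta0: float = 0.45     # ratio at zero prior sleep
    beta1: float = 0.37     # ratio units per unit sleep proportion
    sigma_b: float = 0.05   # per-mouse random-intercept SD
    sigma_e: float = 0.11   # residual SD
    n_mice: int = 11


@dataclass
class RecognitionDataset:
    trials: pd.DataFrame
    recordings: dict = field(default_factory=dict)  # mouse_id -> ActivityRecording
    ground_truth: dict = field(default_factory=dict)


def default_recordings(params: ActivityGenParams | None = None, n_mice: int = 11,
                       seed: int = 0) -> dict:
    """One 7 d LD + 13 d DLE recording per mouse (the study housing design)."""
    from .presets import activity_params  # deferred import: presets imports this module

    schedule = make_schedule("LD", 7) + make_schedule("DLE", 13)
    base = params or activity_params("wt_dle")
    recs = {}
    for i in range(n_mice):
        recs[f"m{i:02d}"] = generate_activity(base, schedule, seed=seed * 1000 + i)
    return recs


def generate_recognition(
    recordings: dict,
    params: RecognitionGenParams | None = None,
    seed: int = 0,
) -> RecognitionDataset:
    """Generate the 8-trial recognition table for each mouse in ``recordings``."""
    params = params or RecognitionGenParams()
    if len(recordings) < 2:
        raise ValueError("need at least 2 mice")
    rng = np.random.default_rng(seed + 7919)
    mice = sorted(recordings)
    b = rng.normal(0.0, params.sigma_b, size=len(mice))
    rows = []
    for mi, mouse in enumerate(mice):
        rec = recordings[mouse]
        sleep = score_sleep(rec)
        for condition, day, zt, stimulus in TRIAL_SCHEDULE:
            t_event = 24.0 * day + zt
            s2h = prior_sleep(sleep, t_event, 2.0)
            eps = rng.normal(0.0, params.sigma_e)
            ratio = float(np.clip(params.beta0 + params.beta1 * s2h + b[mi] + eps, 0.0, 1.0))
            # total exploration per test minute: log-normal, median 20/12/8 s
            totals = [float(np.exp(rng.normal(np.log(m), 0.35))) for m in (20.0, 12.0, 8.0)]
            seg_ratios = [ratio]
            for _ in range(2):  # novelty preference decays toward chance
                seg_ratios.append(float(np.clip(
                    0.5 + 0.4 * (ratio - 0.5) + rng.normal(0.0, 0.05), 0.0, 1.0)))
            row = {
                "mouse_id": mouse,
                "condition": condition,
                "zt": zt,
                "stimulus": stimulus,
                "trial_start_day": day,
                "trial_start_zt": zt,
                "sample_exploration_s": float(np.exp(rng.normal(np.log(27.0), 0.4))),
            }
            for (lo, hi), tot, r in zip(SEGMENTS, totals, seg_ratios):
                row[f"novel_{lo}_{hi}"] = r * tot
                row[f"familiar_{lo}_{hi}"] = (1.0 - r) * tot
            row["true_s2h"] = s2h
            rows.append(row)
    trials = pd.DataFrame(rows)
    truth = {
        "beta0": params.beta0,
        "beta1": params.beta1,
        "sigma_b": params.sigma_b,
        "sigma_e": params.sigma_e,
        "random_intercepts": dict(zip(mice, b)),
    }
    return RecognitionDataset(trials=trials, recordings=dict(recordings), ground_truth=truth)
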