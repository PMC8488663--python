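"""Named generator presets encoding the study conditions.

Each preset programs the effect sizes reported for the corresponding
experimental group, so the downstream pipelines can be validated by
recovering them.  Activity presets program steady-state onset / midpoint /
offset delays (hours vs the LD baseline); the 16:8 long-day preset adds its
extra delay on top of the dim-evening-light (DLE) values so the two presets
contrast directly.
"""

from __future__ import annotations

import dataclasses

from ..schedules import LightSchedule, make_schedule
from .activity import ActivityGenParams
from .bioluminescence import BioluminescenceParams
from .qpcr import RhythmTruth
from .recognition import RecognitionGenParams

TISSUES = ("adrenal", "heart", "hippocampus", "liver")

# steady-state (onset, midpoint, offset) delay targets, hours
_ACTIVITY_TARGETS = {
    "wt_dle": (3.59, 2.57, 2.52),
    "opn4_dle": (2.74, 2.32, 1.61),
    "ld16_8": (3.59 + 2.21, 2.57 + 0.99, 2.52 + 0.64),
}

DD_TAU_H = 23.7
DD_PRIOR_OFFSET_H = 4.0   # programmed prior-DLE vs prior-LD phase difference
BIOLUM_PHI_LD_H = 10.0    # hepatic reporter acrophase, prior-LD group
BIOLUM_DELAY_H = 2.34     # programmed prior-DLE acrophase delay
BIOLUM_TAU_H = 23.7


def activity_params(preset: str, **overrides) -> ActivityGenParams:
    """ActivityGenParams for one of wt_dle, opn4_dle, ld16_8, dd_prior_ld, dd_prior_dle."""
    if preset in _ACTIVITY_TARGETS:
        on, mid, off = _ACTIVITY_TARGETS[preset]
        params = ActivityGenParams(psi_target_h=on, psi_midpoint_target_h=mid,
                                   psi_offset_target_h=off)
    elif preset == "dd_prior_ld":
        params = ActivityGenParams(psi_initial_h=0.0, tau_h=DD_TAU_H)
    elif preset == "dd_prior_dle":
        params = ActivityGenParams(psi_initial_h=DD_PRIOR_OFFSET_H, tau_h=DD_TAU_H)
    else:
        raise ValueError(f"unknown activity preset {preset!r}")
    return dataclasses.replace(params, **overrides) if overrides else params


def study_schedule(preset: str, ld_days: int = 7, treatment_days: int = 13,
                   dd_days: int = 5) -> LightSchedule:
    """Housing schedule matching an activity preset (LD baseline + treatment)."""
    if preset in ("wt_dle", "opn4_dle"):
        return make_schedule("LD", ld_days) + make_schedule("DLE", treatment_days)
    if preset == "ld16_8":
        return make_schedule("LD", ld_days) + make_schedule("LD16_8", treatment_days)
    if preset in ("dd_prior_ld", "dd_prior_dle"):
        return make_schedule("DD", dd_days)
    raise ValueError(f"unknown activity preset {preset!r}")


def bioluminescence_phi(group: str) -> float:
    """Ground-truth acrophase (h) for the prior-LD / prior-DLE reporter groups."""
    if group == "prior_ld":
        return BIOLUM_PHI_LD_H
    if group == "prior_dle":
        return BIOLUM_PHI_LD_H + BIOLUM_DELAY_H
    raise ValueError(f"unknown bioluminescence group {group!r}")


def bioluminescence_params() -> BioluminescenceParams:
    return BioluminescenceParams()


# LD acrophases follow the canonical mouse phase map: Rev-erbalpha peaks
# mid-day, Dbp just before dark onset, Per2 in early night, Bmal1 near dawn.
_GENE_PHASES_LD = {"reverba": 8.0, "dbp": 10.0, "per2": 14.0, "bmal1": 22.0, "cry1": 18.0}
_GENE_SHIFTS = {"reverba": 2.07, "dbp": 1.81, "per2": 1.0, "bmal1": 1.0, "cry1": 1.0}


def gene_shift_truth(gene: str, mesor: float = 1.0, amplitude: float = 0.8) -> dict:
    """Rhythm truth across the four tissues with the gene's programmed shift."""
    if gene not in _GENE_PHASES_LD:
        raise ValueError(f"unknown gene preset {gene!r}")
    phi = _GENE_PHASES_LD[gene]
    shift = _GENE_SHIFTS[gene]
    truth = {}
    for tissue in TISSUES:
        truth[(tissue, gene, "LD")] = RhythmTruth(mesor, amplitude, phi)
        truth[(tissue, gene, "DLE")] = RhythmTruth(mesor, amplitude, phi + shift)
    return truth


def hmgcr_truth(mesor: float = 1.0, amplitude: float = 0.8) -> dict:
    """Liver Hmgcr preset: LD peak at ZT8, delayed to ZT14 under DLE."""
    return {
        ("liver", "hmgcr", "LD"): RhythmTruth(mesor, amplitude, 8.0),
        ("liver", "hmgcr", "DLE"): RhythmTruth(mesor, amplitude, 14.0),
    }


def memory_calibrated_params() -> RecognitionGenParams:
    """Sleep-memory coupling calibrated so group-level R^2(2 h) is ~0.9.

    beta1 is the midpoint of the reported bootstrap CI of the sleep effect;
    sigma_e was set from a single noiseless calibration run of the generator
    (see docs/methods.md) so the expected 8-cell-mean R^2 at the 2-h window
    is about 0.9.
    """
    return RecognitionGenParams(beta0=0.45, beta1=0.37, sigma_b=0.05, sigma_e=0.12)
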