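"""qPCR rhythm normalisation, acrophase (CoG) estimation and phase shifts.

Relative expression uses the comparative threshold-cycle method: each target
Ct is referenced to the geometric mean of two housekeeping genes in the same
sample (2^-dCT), then scaled to the highest cell mean within its lighting
condition (2^-ddCT), so within every tissue x gene x condition the maximal
mean equals 1 exactly.  The acrophase phi of the 24-h rhythm is estimated by
a single-harmonic least-squares fit, with a centre-of-gravity cross-check;
phase shifts wrap phi_DLE - phi_LD into (-12, 12] and pool across tissues
with a two-tailed one-sample t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NormalizedExpression:
    samples: pd.DataFrame   # per-sample rel_expr (2^-dCT) and norm_expr (2^-ddCT)
    cell_means: pd.DataFrame  # mean norm_expr per tissue x gene x condition x zt


@dataclass
class AcrophaseEstimate:
    phi_h: float
    mesor: float
    amplitude: float
    r2: float
    reliable: bool
    cog_fitted_h: float
    cog_raw_h: float


def normalize(table: pd.DataFrame) -> NormalizedExpression:
    """Compute 2^-dCT and condition-peak-normalised 2^-ddCT from a Ct table.

    The geometric mean of housekeeping 2^-CT values equals 2^-mean(CT), which
    is used directly to avoid underflow.  Samples lacking a housekeeping Ct
    are dropped with a warning.
    """
    hk = table[table["role"] == "housekeeping"]
    targets = table[table["role"] == "target"].copy()
    hk_mean = hk.groupby("sample_id")["ct"].agg(["mean", "size"])
    complete = hk_mean.index[hk_mean["size"] >= 2]
    dropped = set(targets["sample_id"]) - set(complete)
    if dropped:
        warnings.warn(f"{len(dropped)} sample(s) missing housekeeping Ct; dropped")
        targets = targets[~targets["sample_id"].isin(dropped)]
    targets["dct"] = targets["ct"] - targets["sample_id"].map(hk_mean["mean"])
    targets["rel_expr"] = 2.0 ** (-targets["dct"])

    key = ["tissue", "gene", "condition"]
    cell = (targets.groupby(key + ["zt"], as_index=False)
            .agg(rel_mean=("rel_expr", "mean"), n=("rel_expr", "size")))
    peak = cell.groupby(key)["rel_mean"].transform("max")
    cell["norm_expr"] = cell["rel_mean"] / peak

    peak_map = cell.set_index(key + ["zt"])["rel_mean"].groupby(key).max()
    targets = targets.merge(peak_map.rename("cond_peak").reset_index(), on=key)
    targets["norm_expr"] = targets["rel_expr"] / targets["cond_peak"]
    return NormalizedExpression(samples=targets, cell_means=cell)


def cog_acrophase(zt, y, period_h: float = 24.0) -> AcrophaseEstimate:
    """Acrophase of a sampled daily profile by single-harmonic least squares.

    Fits ``y = m + a cos(2 pi (zt - phi)/24)`` via the linear cosine/sine
    parameterisation; also reports the centre of gravity (circular mean of
    the ZT angles weighted by the positive part of the rhythm) computed both
    from the fitted wave and from the raw points.  The fit is flagged
    unreliable when the amplitude F test gives p > 0.3.
    """
    zt = np.asarray(zt, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    zt, y = zt[ok], y[ok]
    if len(np.unique(zt % period_h)) < 3:
        raise ValueError("need >= 3 distinct ZT points")
    ang = 2 * np.pi * zt / period_h
    X = np.column_stack([np.ones_like(ang), np.cos(ang), np.sin(ang)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    m, b1, b2 = beta
    amp = float(np.hypot(b1, b2))
    phi = float((np.arctan2(b2, b1) * period_h / (2 * np.pi)) % period_h)
    fit = X @ beta
    sse = float(np.sum((y - fit) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    df_resid = len(y) - 3
    if sst == 0:
        p_amp = 1.0          # flat profile: no rhythm to date
    elif df_resid > 0 and sse > 0:
        f = ((sst - sse) / 2) / (sse / df_resid)
        p_amp = float(stats.f.sf(f, 2, df_resid))
    else:
        p_amp = 0.0 if sse == 0 and amp > 1e-9 else 1.0
    reliable = p_amp <= 0.3

    def _cog(zvals, weights):
        w = np.maximum(weights, 0.0)
        if w.sum() == 0:
            return float("nan")
        a = 2 * np.pi * zvals / period_h
        mean_ang = np.angle(np.sum(w * np.exp(1j * a)))
        return float((mean_ang * period_h / (2 * np.pi)) % period_h)

    zfine = np.linspace(0.0, period_h, 240, endpoint=False)
    wave = m + amp * np.cos(2 * np.pi * (zfine - phi) / period_h)
    cog_fit = _cog(zfine, wave - m)
    cog_raw = _cog(zt, y - m)
    return AcrophaseEstimate(phi_h=phi, mesor=float(m), amplitude=amp, r2=r2,
                             reliable=reliable, cog_fitted_h=cog_fit, cog_raw_h=cog_raw)


def phase_shift(phi_ld: float, phi_dle: float, period_h: float = 24.0) -> float:
    """Delta-phi = phi_DLE - phi_LD wrapped into (-12, 12]."""
    d = (phi_dle - phi_ld) % period_h
    if d > period_h / 2:
        d -= period_h
    return float(d)


@dataclass
class PooledShiftTest:
    mean_h: float
    sem_h: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def pooled_shift_test(delta_phis) -> PooledShiftTest:
    """Two-tailed one-sample t test of pooled phase shifts against zero."""
    d = np.asarray(delta_phis, dtype=float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        raise ValueError("need >= 2 phase-shift values")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    sem = sd / np.sqrt(n)
    if sem == 0.0:
        return PooledShiftTest(mean, 0.0, float("inf") if mean != 0 else 0.0,
                               n - 1, 0.0 if mean != 0 else 1.0, degenerate=True)
    t = mean / sem
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return PooledShiftTest(mean, float(sem), float(t), n - 1, p)


def gene_phase_shifts(norm: NormalizedExpression, gene: str) -> pd.DataFrame:
    """Per-tissue phi_LD, phi_DLE and wrapped delta-phi for one gene."""
    cm = norm.cell_means
    rows = []
    for tissue, sub in cm[cm["gene"] == gene].groupby("tissue"):
        est = {}
        for cond, cs in sub.groupby("condition"):
            est[cond] = cog_acrophase(cs["zt"], cs["norm_expr"])
        if "LD" not in est or "DLE" not in est:
            continue
        dphi = phase_shift(est["LD"].phi_h, est["DLE"].phi_h)
        rows.append({
            "tissue": tissue, "gene": gene,
            "phi_ld": est["LD"].phi_h, "phi_dle": est["DLE"].phi_h,
            "delta_phi": dphi,
            "reliable": est["LD"].reliable and est["DLE"].reliable,
        })
    return pd.DataFrame(rows)
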