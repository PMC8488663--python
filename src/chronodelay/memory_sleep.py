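"""Sleep-history window scan and mixed-effects inference for recognition memory.

The window scan asks how well the sleep proportion in the ``t`` hours before
each recognition trial predicts the recognition ratio, for window widths of
10 min to 3 h in 10-min steps: trials are averaged within the 8 trial-type
cells (2 lighting x 2 ZT x 2 stimulus), an ordinary least-squares line is fit
across the cell means, and R^2(t) is summarised by its quadratic trend and
plateau.  At the individual-trial level, a linear mixed-effects model with a
per-mouse random intercept tests the fixed effect of preceding 2-h sleep via
a maximum-likelihood likelihood-ratio test (1 df), with a parametric
bootstrap percentile CI for the slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .sleep_scoring import prior_sleep

DEFAULT_WIDTHS_MIN = tuple(range(10, 190, 10))


def recognition_ratio(novel_s: float, familiar_s: float) -> float:
    """novel / (novel + familiar); NaN when the segment has no exploration."""
    total = novel_s + familiar_s
    if total <= 0:
        warnings.warn("zero exploration in segment; ratio undefined")
        return float("nan")
    return float(novel_s / total)


def add_ratios(trials: pd.DataFrame, segment=(0, 60)) -> pd.DataFrame:
    """Attach the recognition ratio for one test segment (default 0-60 s)."""
    lo, hi = segment
    out = trials.copy()
    nov = out[f"novel_{lo}_{hi}"].to_numpy(dtype=float)
    fam = out[f"familiar_{lo}_{hi}"].to_numpy(dtype=float)
    total = nov + fam
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(total > 0, nov / total, np.nan)
    return out


def trial_times_h(trials: pd.DataFrame) -> np.ndarray:
    return 24.0 * trials["trial_start_day"].to_numpy() + trials["trial_start_zt"].to_numpy()


def attach_prior_sleep(trials: pd.DataFrame, sleep_by_mouse: dict,
                       widths_min=DEFAULT_WIDTHS_MIN) -> pd.DataFrame:
    """Per-trial prior-sleep proportion for each window width (columns s_<w>)."""
    out = trials.copy()
    times = trial_times_h(out)
    for w in widths_min:
        col = np.empty(len(out))
        for i, (mouse, t) in enumerate(zip(out["mouse_id"], times)):
            col[i] = prior_sleep(sleep_by_mouse[mouse], t, w / 60.0)
        out[f"s_{w}"] = col
    return out


@dataclass
class WindowScanResult:
    widths_min: np.ndarray
    r2: np.ndarray                  # group-level (8 cell means)
    r2_per_case: np.ndarray         # across all individual trials
    quad_coef: np.ndarray           # quadratic trend of R^2 on t (poly order 2)
    r2_at_120: float
    plateau_onset_min: float        # smallest t with R^2 >= 0.95 * max
    cell_means: pd.DataFrame = field(default=None, repr=False)


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0:
        return float("nan")
    r = stats.linregress(x, y)
    return float(r.rvalue ** 2)


def window_scan(trials: pd.DataFrame, sleep_by_mouse: dict,
                widths_min=DEFAULT_WIDTHS_MIN, segment=(0, 60)) -> WindowScanResult:
    """R^2(t) between prior sleep and recognition ratio across window widths."""
    widths = np.asarray(widths_min)
    df = add_ratios(trials, segment)
    df = attach_prior_sleep(df, sleep_by_mouse, widths)
    cells = ["condition", "zt", "stimulus"]
    r2 = np.empty(len(widths))
    r2_case = np.empty(len(widths))
    cm120 = None
    for i, w in enumerate(widths):
        sub = df[np.isfinite(df[f"s_{w}"]) & np.isfinite(df["ratio"])]
        if len(sub) < len(df):
            warnings.warn(f"width {w} min: {len(df) - len(sub)} trial(s) lacked history")
        cm = sub.groupby(cells, as_index=False).agg(
            mean_sleep=(f"s_{w}", "mean"), mean_ratio=("ratio", "mean"))
        r2[i] = _ols_r2(cm["mean_sleep"].to_numpy(), cm["mean_ratio"].to_numpy())
        r2_case[i] = _ols_r2(sub[f"s_{w}"].to_numpy(), sub["ratio"].to_numpy())
        if w == 120:
            cm120 = cm
    quad = np.polyfit(widths, r2, 2)
    peak = np.nanmax(r2)
    above = widths[r2 >= 0.95 * peak]
    plateau = float(above.min()) if len(above) else float("nan")
    r2_120 = float(r2[widths == 120][0]) if (widths == 120).any() else float("nan")
    return WindowScanResult(widths_min=widths, r2=r2, r2_per_case=r2_case,
                            quad_coef=quad, r2_at_120=r2_120,
                            plateau_onset_min=plateau, cell_means=cm120)


@dataclass
class LMMResult:
    slope: float
    slope_se: float
    sigma_b2: float
    sigma_e2: float
    chi2: float
    p: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    singular: bool = False
    intercept: float = float("nan")


def _fit_ml(y, x, groups):
    """One ML random-intercept fit; returns (llf, params...) or raises."""
    exog = np.column_stack([np.ones_like(x), x]) if x is not None else np.ones((len(y), 1))
    model = MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False)
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell")
    return res


def fit_lmm(y, x, groups, n_boot: int = 0, seed: int = 0) -> LMMResult:
    """Random-intercept LMM of y on x with an ML likelihood-ratio test for x.

    ``chi2`` is deviance(null) - deviance(full) on 1 df.  When ``n_boot`` > 0
    a parametric bootstrap (simulate from the fitted full model, refit,
    percentile CI of the slope) supplies the 95% CI.  Singular random-effect
    fits fall back to ordinary least squares with ``singular=True``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x, groups = y[ok], x[ok], groups[ok]
    if np.ptp(x) == 0:
        full = _fit_ml(y, None, groups)
        return LMMResult(slope=0.0, slope_se=float("nan"), sigma_b2=float(np.asarray(full.cov_re)[0, 0]),
                         sigma_e2=float(full.scale), chi2=0.0, p=1.0,
                         intercept=float(full.fe_params[0]))
    try:
        full = _fit_ml(y, x, groups)
        null = _fit_ml(y, None, groups)
        chi2 = max(0.0, 2.0 * (full.llf - null.llf))
        slope = float(full.fe_params[1])
        slope_se = float(full.bse_fe[1])
        sigma_b2 = float(np.asarray(full.cov_re)[0, 0])
        sigma_e2 = float(full.scale)
        intercept = float(full.fe_params[0])
        singular = False
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("singular mixed-model fit; falling back to ordinary regression")
        r = stats.linregress(x, y)
        resid = y - (r.intercept + r.slope * x)
        n = len(y)
        ll_full = -0.5 * n * (np.log(2 * np.pi * resid.var()) + 1)
        resid0 = y - y.mean()
        ll_null = -0.5 * n * (np.log(2 * np.pi * resid0.var()) + 1)
        chi2 = max(0.0, 2.0 * (ll_full - ll_null))
        slope, slope_se, intercept = float(r.slope), float(r.stderr), float(r.intercept)
        sigma_b2, sigma_e2 = 0.0, float(resid.var())
        singular = True
    p = float(stats.chi2.sf(chi2, 1))
    res = LMMResult(slope=slope, slope_se=slope_se, sigma_b2=sigma_b2,
                    sigma_e2=sigma_e2, chi2=chi2, p=p, singular=singular,
                    intercept=intercept)
    if n_boot > 0:
        res.ci_low, res.ci_high = _parametric_bootstrap_ci(
            res, x, groups, n_boot, seed)
        res.n_boot = n_boot
    return res


def _parametric_bootstrap_ci(fit: LMMResult, x, groups, n_boot: int, seed: int,
                             level: float = 0.95):
    """Percentile CI of the slope from simulations of the fitted full model."""
    rng = np.random.default_rng(seed)
    uniq, gidx = np.unique(groups, return_inverse=True)
    mean = fit.intercept + fit.slope * x
    sb = np.sqrt(max(fit.sigma_b2, 0.0))
    se = np.sqrt(max(fit.sigma_e2, 0.0))
    slopes = np.empty(n_boot)
    i = 0
    attempts = 0
    while i < n_boot and attempts < 3 * n_boot:
        attempts += 1
        b = rng.normal(0.0, sb, len(uniq))
        ysim = mean + b[gidx] + rng.normal(0.0, se, len(x))
        try:
            res = _fit_ml(ysim, x, groups)
            slopes[i] = res.fe_params[1]
            i += 1
        except (np.linalg.LinAlgError, ValueError):
            continue  # failed refit: resample
    slopes = slopes[:i]
    alpha = 1.0 - level
    return (float(np.quantile(slopes, alpha / 2)),
            float(np.quantile(slopes, 1 - alpha / 2)))


def lmm_sleep_effect(trials: pd.DataFrame, sleep_by_mouse: dict,
                     n_boot: int = 0, seed: int = 0, segment=(0, 60)) -> LMMResult:
    """Effect of preceding 2-h sleep on the recognition ratio."""
    df = add_ratios(trials, segment)
    df = attach_prior_sleep(df, sleep_by_mouse, widths_min=(120,))
    return fit_lmm(df["ratio"], df["s_120"], df["mouse_id"], n_boot=n_boot, seed=seed)


def exploration_effects(trials: pd.DataFrame, sleep_by_mouse: dict,
                        n_boot: int = 0, seed: int = 0, segment=(0, 60)):
    """(sleep -> sample exploration, sample exploration -> ratio) mixed models."""
    df = add_ratios(trials, segment)
    df = attach_prior_sleep(df, sleep_by_mouse, widths_min=(120,))
    sleep_to_expl = fit_lmm(df["sample_exploration_s"], df["s_120"], df["mouse_id"],
                            n_boot=n_boot, seed=seed)
    expl_to_ratio = fit_lmm(df["ratio"], df["sample_exploration_s"], df["mouse_id"],
                            n_boot=n_boot, seed=seed + 1)
    return sleep_to_expl, expl_to_ratio
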