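"""Quality-control figures: double-plotted actograms and the R^2(t) curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def double_plotted_actogram(recording, markers=None, ax=None, bin_min: int = 6):
    """Raster of activity with 48-h rows on the ZT6-ZT30 axis.

    Each row shows two consecutive days so the nocturnal bout is never split;
    optional phase-marker table overlays onset/midpoint/offset traces.
    """
    counts = np.asarray(recording.counts, dtype=float)
    n_per_day = int(24 * 3600 / recording.bin_width_s)
    n_days = len(counts) // n_per_day
    # rebin to bin_min resolution
    cols = int(24 * 60 / bin_min)
    day_mat = counts[: n_days * n_per_day].reshape(n_days, cols, -1).sum(axis=2)
    # shift so each row starts at ZT6, then pair days
    shift = int(6 * 60 / bin_min)
    rows = []
    for d in range(n_days - 1):
        row = np.concatenate([day_mat[d], day_mat[d + 1]])[shift:shift + 2 * cols]
        rows.append(row)
    mat = np.vstack(rows) if rows else day_mat
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.35 * max(len(rows), 1) + 1))
    ax.imshow(mat, aspect="auto", cmap="viridis", interpolation="nearest",
              extent=[6, 54, n_days - 1, 0])
    if markers is not None:
        for col, style in (("onset_zt", "w--"), ("midpoint_zt", "w-"), ("offset_zt", "w--")):
            ax.plot(markers[col], markers["day"] + 0.5, style, linewidth=1)
    ax.set_xlabel("ZT (h; rows span 48 h from ZT6)")
    ax.set_ylabel("day")
    return ax


def r2_curve(scan, ax=None):
    """R^2 against window width with its quadratic trend, 2-h point marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    w = np.asarray(scan.widths_min, dtype=float)
    ax.plot(w, scan.r2, "o-", label=r"$R^2(t)$")
    ax.plot(w, np.polyval(scan.quad_coef, w), "--", label="quadratic trend")
    if (w == 120).any():
        ax.plot(120, scan.r2_at_120, "m*", markersize=12, label=r"$t = 2$ h")
    ax.set_xlabel("window width t (min)")
    ax.set_ylabel(r"group-level $R^2$")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower right", fontsize=8)
    return ax
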