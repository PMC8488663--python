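"""Synthetic qPCR Ct tables with cosine-shaped clock-gene expression.

Target-gene expression follows ``mesor + amplitude * cos(2*pi*(ZT - phi)/24)``
per tissue x gene x condition; the threshold cycle is ``c0 - log2(expression)``
plus Gaussian Ct noise.  Two housekeeping genes with constant expression are
attached to every sample, matching the geometric-mean normalisation used
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLED_ZTS = (2, 8, 14, 20)
HOUSEKEEPING = {"Tbp": 24.0, "Gapdh": 18.0}  # constant Ct levels


@dataclass(frozen=True)
class RhythmTruth:
    """Ground-truth rhythm for one tissue x gene x condition."""

    mesor: float
    amplitude: float
    phi_h: float

    def __post_init__(self):
        if self.amplitude >= self.mesor:
            raise ValueError("amplitude must be < mesor (expression must stay positive)")

    def expression(self, zt) -> np.ndarray:
        zt = np.asarray(zt, dtype=float)
        return self.mesor + self.amplitude * np.cos(2 * np.pi * (zt - self.phi_h) / 24.0)


def generate_qpcr(
    rhythm_truth: dict,
    noise_sd_ct: float = 0.15,
    n_replicates=4,
    c0: float = 22.0,
    zts=SAMPLED_ZTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a long-format Ct table.

    Parameters
    ----------
    rhythm_truth : dict
        ``{(tissue, gene, condition): RhythmTruth}``.
    noise_sd_ct : float
        Gaussian SD added to every Ct value (cycles).
    n_replicates : int or dict
        Animals per (tissue, gene, condition, ZT) cell; a dict keyed by
        ``(tissue, gene, condition, zt)`` allows the sparse cells (n = 2-3)
        seen in real designs.
    """
    if noise_sd_ct < 0:
        raise ValueError("noise_sd_ct must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    sample_counter = 0
    for (tissue, gene, condition), truth in sorted(rhythm_truth.items()):
        for zt in zts:
            if isinstance(n_replicates, dict):
                n_rep = n_replicates.get((tissue, gene, condition, zt), 4)
            else:
                n_rep = n_replicates
            expr = float(truth.expression(zt))
            for _ in range(n_rep):
                sample_id = f"s{sample_counter:05d}"
                sample_counter += 1
                ct_target = c0 - np.log2(expr) + rng.normal(0.0, noise_sd_ct)
                rows.append((sample_id, tissue, condition, zt, gene, "target", ct_target))
                for hk, level in HOUSEKEEPING.items():
                    ct_hk = level + rng.normal(0.0, noise_sd_ct)
                    rows.append((sample_id, tissue, condition, zt, hk, "housekeeping", ct_hk))
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "condition", "zt", "gene", "role", "ct"]
    )
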