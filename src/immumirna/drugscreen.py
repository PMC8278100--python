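"""Risk-associated drug selection from an imputed IC50 table.

A drug is tied to the risk signature when it passes two criteria at once:
(1) the Pearson correlation between its (log-scale) IC50 and the continuous
risk score exceeds ``r_min`` in magnitude with BH-FDR below ``alpha`` across
drugs, and (2) the high-vs-low risk group difference of mean log2 IC50
exceeds ``fc_min`` in magnitude with Welch-t BH-FDR below ``alpha``. Lower
IC50 means greater sensitivity, so a negative correlation marks drugs the
high-risk group is more sensitive to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

__all__ = ["DrugScreenConfig", "drug_screen"]


@dataclass
class DrugScreenConfig:
    """Selection thresholds of the dual-criterion screen."""

    r_min: float = 0.3
    fc_min: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.r_min < 1):
            raise ValueError("r_min must lie in [0, 1)")
        if self.fc_min < 0:
            raise ValueError("fc_min must be ≥ 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")


def drug_screen(
    ic50: pd.DataFrame,
    scores: pd.Series,
    groups: pd.Series,
    config: DrugScreenConfig | None = None,
) -> pd.DataFrame:
    """Select drugs associated with the risk score by the dual criterion.

    ``ic50`` is drugs × samples on a log2 scale, ``scores`` the continuous
    risk score and ``groups`` the high/low assignment per sample. Returns a
    table (drug_id, r, r_fdr, log2fc, t_fdr, selected) in the input drug
    order; drugs with constant IC50 are excluded with a warning since their
    correlation is undefined. The result does not depend on drug row order.
    """
    config = config or DrugScreenConfig()
    if ic50.index.has_duplicates:
        raise ValueError("duplicate drug ids in IC50 table")
    samples = [s for s in ic50.columns if s in scores.index and s in groups.index]
    if len(samples) < 6:
        raise ValueError(f"need at least 6 shared samples, got {len(samples)}")
    values = ic50.loc[:, samples].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("IC50 table contains non-finite values")
    score_vec = scores.loc[samples].to_numpy(dtype=float)
    group_vec = groups.loc[samples].astype(str).to_numpy()
    high = group_vec == "high"
    if high.sum() < 3 or (~high).sum() < 3:
        raise ValueError("need at least 3 samples per risk group")

    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant IC50 row(s): "
            f"{ic50.index[constant].tolist()[:5]}",
            UserWarning,
            stacklevel=2,
        )
    kept = ic50.index[~constant]
    vals = values[~constant]

    centered = vals - vals.mean(axis=1, keepdims=True)
    s_centered = score_vec - score_vec.mean()
    r = (centered @ s_centered) / (
        np.sqrt((centered**2).sum(axis=1)) * np.sqrt((s_centered**2).sum())
    )
    n = len(samples)
    r_clip = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    t_r = r_clip * np.sqrt((n - 2) / (1 - r_clip**2))
    p_r = 2 * stats.t.sf(np.abs(t_r), n - 2)

    t_stat, p_t = stats.ttest_ind(
        vals[:, high], vals[:, ~high], axis=1, equal_var=False
    )
    log2fc = vals[:, high].mean(axis=1) - vals[:, ~high].mean(axis=1)

    r_fdr = bh_fdr(np.maximum(p_r, 1e-300))
    t_fdr = bh_fdr(np.maximum(p_t, 1e-300))
    selected = (
        (np.abs(r) > config.r_min)
        & (r_fdr < config.alpha)
        & (np.abs(log2fc) > config.fc_min)
        & (t_fdr < config.alpha)
    )
    return pd.DataFrame(
        {
            "drug_id": kept,
            "r": r,
            "r_fdr": r_fdr,
            "log2fc": log2fc,
            "t_fdr": t_fdr,
            "selected": selected,
        }
    ).reset_index(drop=True)
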