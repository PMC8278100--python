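"""Prognostic risk scoring from a linear miRNA signature, survival-optimal
cutpoint selection, risk-group assignment and log-rank comparison.

The risk score of a sample is the coefficient-weighted sum of its
standardized (z-scored) signature-miRNA expression,

    score_s = Σ_i Exp_is × Coef_i .

The package ships the three-miRNA immune-associated prognostic signature
(IAMIPS) with its published training constants: coefficients 0.015 for
miR-216a-5p, −0.035 for miR-194-3p and −0.124 for miR-3677-3p, and risk-score
cutoff 0.05. Samples scoring strictly above the cutoff form the high-risk
group. On a new cohort the cutoff can instead be re-derived by the maximally
selected log-rank statistic: every admissible split of the observed scores is
evaluated and the cutpoint with the largest two-group log-rank chi-square is
returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .io_prep import ExpressionMatrix, SurvivalData

__all__ = [
    "SignatureModel",
    "load_signature",
    "save_signature",
    "load_iamips",
    "risk_score",
    "log_rank_statistic",
    "optimal_cutpoint",
    "assign_groups",
]


@dataclass
class SignatureModel:
    """A linear risk signature: (miRNA, coefficient) entries plus a cutoff."""

    entries: list[tuple[str, float]]
    cutoff: float
    name: str = "signature"

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in signature")
        if not all(np.isfinite(c) for _, c in self.entries):
            raise ValueError("signature coefficients must be finite")
        if not np.isfinite(self.cutoff):
            raise ValueError("signature cutoff must be finite")

    @property
    def mirna_ids(self) -> list[str]:
        return [m for m, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.entries], dtype=float)


def load_signature(path, name: str | None = None) -> SignatureModel:
    """Read a signature file: a ``cutoff=<value>`` metadata line, a
    ``mirna_id<TAB>coefficient`` header, then one entry per line."""
    cutoff = None
    entries: list[tuple[str, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("cutoff="):
                cutoff = float(line.split("=", 1)[1])
                continue
            fields = line.replace(",", "\t").split("\t")
            if fields[0] == "mirna_id":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected (mirna_id, coefficient)")
            entries.append((fields[0], float(fields[1])))
    if cutoff is None:
        raise ValueError(f"{path}: missing 'cutoff=<value>' metadata line")
    if not entries:
        raise ValueError(f"{path}: signature has no entries")
    return SignatureModel(entries, cutoff, name or str(path))


def save_signature(signature: SignatureModel, path) -> None:
    with open(path, "w") as handle:
        handle.write(f"cutoff={signature.cutoff:g}\n")
        handle.write("mirna_id\tcoefficient\n")
        for mirna_id, coef in signature.entries:
            handle.write(f"{mirna_id}\t{coef:g}\n")


def load_iamips() -> SignatureModel:
    """The packaged three-miRNA IAMIPS signature with its training constants."""
    path = resources.files("immumirna").joinpath("data/iamips_tcga.tsv")
    with resources.as_file(path) as p:
        return load_signature(p, name="iamips_tcga")


def risk_score(z_expr: ExpressionMatrix, signature: SignatureModel) -> pd.Series:
    """Per-sample risk score Σ_i Exp_is × Coef_i on z-scored expression.

    Every signature miRNA must be present in the matrix; missing ids raise
    with the full list. Non-z-scored input is allowed but warned about,
    since the packaged coefficients were trained on standardized expression.
    """
    if z_expr.state != "zscore":
        warnings.warn(
            f"risk score expects z-scored expression, got state {z_expr.state!r}",
            UserWarning,
            stacklevel=2,
        )
    missing = [m for m in signature.mirna_ids if m not in z_expr.values.index]
    if missing:
        raise ValueError(f"signature miRNA(s) absent from matrix: {missing}")
    sub = z_expr.values.loc[signature.mirna_ids]
    scores = sub.T @ signature.coefficients
    scores.name = "risk_score"
    return scores


def log_rank_statistic(survival: SurvivalData, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value.

    ``groups`` maps sample ids to exactly two labels; both groups must be
    non-empty. If no events occurred at all the statistic is 0 (p = 1) with
    a warning.
    """
    groups = groups.loc[survival.time.index]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    mask = (groups == labels[0]).to_numpy()
    if survival.event.sum() == 0:
        warnings.warn("no events in either group; log-rank statistic is 0",
                      UserWarning, stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(
        survival.time.to_numpy()[mask],
        survival.time.to_numpy()[~mask],
        event_observed_A=survival.event.to_numpy()[mask],
        event_observed_B=survival.event.to_numpy()[~mask],
    )
    return float(res.test_statistic), float(res.p_value)


def _logrank_chi2_profile(
    time: np.ndarray, event: np.ndarray, scores: np.ndarray, candidates: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square of the split ``score > c`` for every candidate c.

    Vectorized over candidates: at each distinct event time t, the at-risk
    and death counts of the high group are inner products of the at-risk /
    death indicator with the candidate membership matrix.
    """
    event_times = np.unique(time[event == 1])
    at_risk = time[None, :] >= event_times[:, None]  # (J, n)
    deaths = (time[None, :] == event_times[:, None]) & (event[None, :] == 1)
    n_j = at_risk.sum(axis=1).astype(float)
    d_j = deaths.sum(axis=1).astype(float)
    high = (scores[:, None] > candidates[None, :]).astype(float)  # (n, C)
    n1 = at_risk.astype(float) @ high  # (J, C)
    d1 = deaths.astype(float) @ high
    frac = n1 / n_j[:, None]
    o_minus_e = (d1 - d_j[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = (
            d_j[:, None]
            * frac
            * (1.0 - frac)
            * ((n_j[:, None] - d_j[:, None]) / np.maximum(n_j[:, None] - 1.0, 1.0))
        )
    var = np.nan_to_num(var_terms).sum(axis=0)
    chi2 = np.zeros_like(var)
    nonzero = var > 0
    chi2[nonzero] = o_minus_e[nonzero] ** 2 / var[nonzero]
    return chi2


def optimal_cutpoint(
    scores: pd.Series, survival: SurvivalData, minprop: float = 0.1
) -> float:
    """Maximally selected log-rank cutpoint for a continuous risk score.

    Candidate cutpoints are midpoints of adjacent sorted unique scores whose
    induced groups each hold at least ``minprop`` of the subjects; the
    candidate with the largest log-rank chi-square wins, ties going to the
    smaller cutpoint. Requires at least 10 subjects.
    """
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must lie in (0, 0.5)")
    scores = scores.loc[survival.time.index]
    n = len(scores)
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    values = scores.to_numpy(dtype=float)
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("scores are constant; no cutpoint exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_high = (values[:, None] > candidates[None, :]).sum(axis=0)
    feasible = (n_high >= minprop * n) & ((n - n_high) >= minprop * n)
    candidates = candidates[feasible]
    if candidates.size == 0:
        raise ValueError(f"no candidate cutpoint leaves ≥ {minprop:.0%} per group")
    chi2 = _logrank_chi2_profile(
        survival.time.to_numpy(dtype=float),
        survival.event.to_numpy(dtype=int),
        values,
        candidates,
    )
    return float(candidates[int(np.argmax(chi2))])


def assign_groups(scores: pd.Series, cutoff: float) -> pd.DataFrame:
    """Split samples into risk groups: score > cutoff → high, else low."""
    group = np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low")
    return pd.DataFrame(
        {"score": scores.to_numpy(dtype=float), "group": group}, index=scores.index
    ).rename_axis("sample_id")
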