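"""Purity-adjusted miRNA–gene association statistics.

Bulk tumour samples are mixtures of malignant and non-malignant cells, so a
miRNA and a gene can correlate merely because both track tumour purity. The
first-order partial correlation removes that shared component: with R_MG the
Pearson correlation between miRNA and gene, and R_MP, R_GP their respective
correlations with purity,

    PCC = (R_MG − R_MP·R_GP) / (sqrt(1 − R_MP²)·sqrt(1 − R_GP²)).

A two-sided p-value comes from the t statistic PCC·sqrt((n−3)/(1−PCC²)) on
n−3 degrees of freedom (one covariate partialled out). Each gene is then
scored by the signed log p-value

    RS = −log10(p) × sign(PCC),

and the genes ranked by RS (large positive RS first) form the input to the
enrichment stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_prep import ExpressionMatrix, PurityVector

__all__ = [
    "AssociationRecord",
    "RankedGeneList",
    "partial_correlation",
    "rank_score",
    "rank_genes",
    "associate_all",
]

P_FLOOR = 1e-300  # keeps −log10(p) finite; RS is only used for ordering/weights


@dataclass
class AssociationRecord:
    """Association statistics for one miRNA–gene pair."""

    mirna_id: str
    gene_id: str
    r_mg: float
    r_mp: float
    r_gp: float
    pcc: float
    p: float
    rs: float
    n: int


@dataclass
class RankedGeneList:
    """Genes of one miRNA ordered by rank score, descending.

    Ties in RS are broken by gene id (ascending) so the ordering is
    deterministic regardless of input order.
    """

    mirna_id: str
    gene_ids: list
    rs: np.ndarray

    def __post_init__(self) -> None:
        self.rs = np.asarray(self.rs, dtype=float)
        if len(self.gene_ids) != self.rs.size:
            raise ValueError("gene_ids and rs lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.rs) > 1e-12):
            raise ValueError("rank scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _check_vector(name: str, v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    if np.ptp(v) == 0:
        raise ValueError(f"{name} is constant; correlation undefined")
    return v


def partial_correlation(x, y, c) -> tuple[float, float, int]:
    """First-order partial correlation of x and y controlling for c.

    Returns ``(pcc, p, n)`` where p is the two-sided p-value of the t
    statistic on n−3 degrees of freedom. Requires n ≥ 4 and non-constant
    vectors; |corr(x,c)| = 1 or |corr(y,c)| = 1 makes the denominator zero
    and is an error.
    """
    x = _check_vector("x", x)
    y = _check_vector("y", y)
    c = _check_vector("c", c)
    n = x.size
    if y.size != n or c.size != n:
        raise ValueError("x, y and c must have equal length")
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    r_mg = float(np.corrcoef(x, y)[0, 1])
    r_mp = float(np.corrcoef(x, c)[0, 1])
    r_gp = float(np.corrcoef(y, c)[0, 1])
    denom = (1.0 - r_mp**2) * (1.0 - r_gp**2)
    if denom <= 0:
        raise ValueError("x or y is perfectly correlated with the covariate")
    pcc = (r_mg - r_mp * r_gp) / np.sqrt(denom)
    pcc = float(np.clip(pcc, -1.0, 1.0))
    p = _pcc_pvalue(np.array([pcc]), n, df=n - 3)[0]
    return pcc, float(p), n


def _pcc_pvalue(pcc: np.ndarray, n: int, df: int) -> np.ndarray:
    """Two-sided p-value for (partial) correlations via the t transform."""
    clipped = np.clip(pcc, -1.0 + 1e-12, 1.0 - 1e-12)
    t = clipped * np.sqrt(df / (1.0 - clipped**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.maximum(p, P_FLOOR)


def rank_score(p: float, pcc: float) -> float:
    """Signed log p-value: −log10(p) × sign(pcc); p is floored at 1e-300."""
    if p <= 0:
        raise ValueError(f"p must be positive, got {p}")
    if p > 1:
        raise ValueError(f"p must be ≤ 1, got {p}")
    return float(-np.log10(max(p, P_FLOOR)) * np.sign(pcc))


def rank_genes(records) -> RankedGeneList:
    """Order one miRNA's association records by rank score, descending.

    Accepts an iterable of :class:`AssociationRecord` (all for the same
    miRNA). Ties are broken by gene id ascending.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to rank")
    mirna_ids = {r.mirna_id for r in records}
    if len(mirna_ids) != 1:
        raise ValueError(f"records span multiple miRNAs: {sorted(mirna_ids)}")
    gene_ids = [r.gene_id for r in records]
    if len(set(gene_ids)) != len(gene_ids):
        dup = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene id(s): {dup}")
    order = sorted(records, key=lambda r: (-r.rs, r.gene_id))
    return RankedGeneList(
        mirna_id=records[0].mirna_id,
        gene_ids=[r.gene_id for r in order],
        rs=np.array([r.rs for r in order]),
    )


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of `a` with every row of `b`."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    a_norm = np.sqrt((a**2).sum(axis=1))
    b_norm = np.sqrt((b**2).sum(axis=1))
    if np.any(a_norm == 0) or np.any(b_norm == 0):
        raise ValueError("constant feature row; correlation undefined")
    return (a @ b.T) / np.outer(a_norm, b_norm)


def associate_all(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    purity: PurityVector | None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Purity-adjusted association of every miRNA with every gene.

    Inputs must already share the same sample columns in the same order
    (see :func:`immumirna.io_prep.align_samples`). Returns three DataFrames
    (miRNA × gene): the partial correlation, its two-sided p-value, and the
    rank score. When purity is ``None`` the statistics fall back to the plain
    Pearson correlation (p from the t test on n−2 df) with a warning.
    """
    if mirna.sample_ids != mrna.sample_ids:
        raise ValueError("miRNA and mRNA matrices must share sample order")
    n = len(mirna.sample_ids)
    if n < 4:
        raise ValueError(f"need at least 4 shared samples, got {n}")
    m = mirna.values.to_numpy(dtype=float)
    g = mrna.values.to_numpy(dtype=float)
    r_mg = _row_correlations(m, g)
    if purity is None:
        warnings.warn(
            "no purity vector supplied; falling back to plain Pearson correlation",
            UserWarning,
            stacklevel=2,
        )
        pcc = np.clip(r_mg, -1.0, 1.0)
        p = _pcc_pvalue(pcc, n, df=n - 2)
    else:
        if purity.sample_ids != mirna.sample_ids:
            raise ValueError("purity vector must share the matrices' sample order")
        c = purity.purity.to_numpy(dtype=float)[None, :]
        r_mp = _row_correlations(m, c)[:, 0]
        r_gp = _row_correlations(g, c)[:, 0]
        if np.any(np.abs(r_mp) >= 1.0) or np.any(np.abs(r_gp) >= 1.0):
            raise ValueError("a feature is perfectly correlated with purity")
        denom = np.outer(np.sqrt(1.0 - r_mp**2), np.sqrt(1.0 - r_gp**2))
        pcc = np.clip((r_mg - np.outer(r_mp, r_gp)) / denom, -1.0, 1.0)
        p = _pcc_pvalue(pcc, n, df=n - 3)
    rs = -np.log10(p) * np.sign(pcc)
    index = mirna.values.index
    columns = mrna.values.index
    return (
        pd.DataFrame(pcc, index=index, columns=columns),
        pd.DataFrame(p, index=index, columns=columns),
        pd.DataFrame(rs, index=index, columns=columns),
    )
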