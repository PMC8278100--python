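"""Gene-set enrichment scoring on ranked gene lists, permutation nulls,
the miRES statistic, and per-sample (ssGSEA-style) scoring.

For one miRNA the genes are ordered by rank score (RS) and a weighted
Kolmogorov–Smirnov running sum is computed for each immune pathway: walking
down the ranked list, members of the pathway advance the sum by
|RS|^w / Σ_hits |RS|^w and non-members retreat by 1/(N − N_hit). The
enrichment score (ES) is the signed deviation of maximal absolute value.

Significance comes from a gene-set permutation null — random same-size sets
drawn from the ranked universe — conditioned on the sign of the observed ES,
with the usual +1 pseudocount so p ∈ (0, 1]. ES and p combine into

    miRES = 1 − 2p  if ES > 0,
            2p − 1  if ES < 0,

which lives in [−1, 1] and carries the ES sign. A miRNA–pathway pair is
called significant when |miRES| exceeds the miRES threshold (default 0.995)
and its Benjamini–Hochberg FDR across all scanned pairs is below the FDR
threshold (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .assoc import associate_all
from .io_prep import ExpressionMatrix, GeneSetCollection, PurityVector

__all__ = [
    "EnrichmentRecord",
    "ScanConfig",
    "enrichment_score",
    "permutation_test",
    "mires",
    "bh_fdr",
    "immu_mirna_scan",
    "records_to_frame",
    "ssgsea",
]

_NULL_CHUNK = 4096  # permutation rows per vectorized block (memory bound)


@dataclass
class EnrichmentRecord:
    """Enrichment result for one miRNA–pathway pair."""

    mirna_id: str
    pathway: str
    es: float
    p: float
    fdr: float
    mires: float
    significant: bool


@dataclass
class ScanConfig:
    """Tunables of the miRNA × pathway scan.

    ``n_perm`` permutations are drawn for every pair; pairs whose
    same-sign exceedance count falls at or below ``refine_count`` are
    re-estimated with ``n_perm_refine`` fresh permutations, so small
    p-values get the resolution the dual significance threshold needs
    without paying the refined cost everywhere.
    """

    seed: int
    n_perm: int = 1000
    weight_exponent: float = 1.0
    mires_threshold: float = 0.995
    fdr_threshold: float = 0.05
    n_perm_refine: int = 20000
    refine_count: int = 9

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not (0 <= self.mires_threshold <= 1):
            raise ValueError("mires_threshold must lie in [0, 1]")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _es_from_positions(weights: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Signed max-deviation ES for hit positions on a ranked list.

    ``weights`` is the per-position weight vector (|RS|^w) of the full
    ranked list; ``positions`` is a (P, k) array of sorted hit positions,
    one row per (permuted) gene set. Only the running sum's local extrema —
    just before and just after each hit — can attain the maximal deviation,
    so the scan is O(k) per set instead of O(N).
    """
    n_total = weights.size
    k = positions.shape[1]
    w = weights[positions]  # (P, k)
    total = w.sum(axis=1)
    # all-zero hit weights: fall back to unweighted (classic KS) steps
    zero_rows = total == 0
    if zero_rows.any():
        w = np.where(zero_rows[:, None], 1.0, w)
        total = np.where(zero_rows, float(k), total)
    cum = np.cumsum(w, axis=1)
    miss_step = 1.0 / (n_total - k) if n_total > k else 0.0
    misses_before = positions - np.arange(k)
    retreat = misses_before * miss_step
    dev_after = cum / total[:, None] - retreat
    dev_before = (cum - w) / total[:, None] - retreat
    cand = np.concatenate([dev_after, dev_before], axis=1)
    max_dev = cand.max(axis=1)
    min_dev = cand.min(axis=1)
    # the signed deviation of maximal absolute value; ties (to rounding) go
    # positive so the sign is deterministic
    return np.where(max_dev >= -min_dev - 1e-12, max_dev, min_dev)


def _hit_positions(ranked_gene_ids, gene_set) -> np.ndarray:
    index = {g: i for i, g in enumerate(ranked_gene_ids)}
    pos = sorted(index[g] for g in gene_set if g in index)
    return np.asarray(pos, dtype=np.intp)


def enrichment_score(ranked, gene_set, weight_exponent: float = 1.0) -> float:
    """Weighted KS enrichment score of a gene set on a ranked list.

    ``ranked`` is a :class:`~immumirna.assoc.RankedGeneList` (or any object
    with ``gene_ids`` and ``rs``). With ``weight_exponent=0`` this reduces to
    the classic unweighted KS statistic. An empty intersection between the
    set and the ranked universe is an error; if every hit weight is zero at
    a positive exponent, the unweighted statistic is used with a warning.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be ≥ 0")
    rs = np.asarray(ranked.rs, dtype=float)
    pos = _hit_positions(ranked.gene_ids, gene_set)
    if pos.size == 0:
        raise ValueError("gene set has no members in the ranked list")
    weights = np.abs(rs) ** weight_exponent
    if weight_exponent > 0 and weights[pos].sum() == 0:
        warnings.warn(
            "all hit weights are zero; falling back to unweighted statistic",
            UserWarning,
            stacklevel=2,
        )
    return float(_es_from_positions(weights, pos[None, :])[0])


def _null_es(
    weights: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES values of ``n_perm`` random same-size sets from the universe."""
    n_total = weights.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        block = min(_NULL_CHUNK, n_perm - done)
        keys = rng.random((block, n_total), dtype=np.float32)
        pos = np.argpartition(keys, set_size, axis=1)[:, :set_size]
        pos.sort(axis=1)
        out[done : done + block] = _es_from_positions(weights, pos)
        done += block
    return out


def _permutation_p(obs: float, null: np.ndarray) -> float:
    """Same-sign conditioned permutation p with a +1 pseudocount."""
    if obs == 0:
        return 1.0
    same = np.sign(null) == np.sign(obs)
    exceed = same & (np.abs(null) >= abs(obs))
    return float((1 + exceed.sum()) / (1 + same.sum()))


def permutation_test(
    ranked,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> float:
    """Gene-set permutation p-value of the observed enrichment score.

    The null is built from ``n_perm`` random gene sets of the same size
    drawn from the ranked universe; p counts same-sign null scores at least
    as extreme as the observed one, with a +1 pseudocount in numerator and
    denominator so p ∈ (0, 1]. Identical seeds give identical p-values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rs = np.asarray(ranked.rs, dtype=float)
    pos = _hit_positions(ranked.gene_ids, gene_set)
    if pos.size >= rs.size:
        raise ValueError(
            f"set size {pos.size} must be smaller than the universe {rs.size}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        obs = enrichment_score(ranked, gene_set, weight_exponent)
    weights = np.abs(rs) ** weight_exponent
    rng = np.random.default_rng(seed)
    null = _null_es(weights, pos.size, n_perm, rng)
    return _permutation_p(obs, null)


def mires(es: float, p: float) -> float:
    """Combine an enrichment score's sign with its permutation p-value.

    Returns 1 − 2p for positive ES and 2p − 1 for negative ES, so the score
    lives in [−1, 1], approaches ±1 as p → 0 and is 0 at p = 1/2. ES = 0 is
    undefined and raises.
    """
    if es == 0:
        raise ValueError("miRES is undefined for an enrichment score of 0")
    if not (0 < p <= 1):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return 1.0 - 2.0 * p if es > 0 else 2.0 * p - 1.0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full scan
# ---------------------------------------------------------------------------


def immu_mirna_scan(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    purity: PurityVector | None,
    gene_sets: GeneSetCollection,
    config: ScanConfig,
) -> list[EnrichmentRecord]:
    """Score every miRNA × pathway pair for purity-adjusted regulation.

    For each miRNA: partial correlations against all genes → rank scores →
    ranked gene list → per-pathway ES and permutation p → miRES. FDR is
    Benjamini–Hochberg across all miRNA–pathway pairs of the scan, and a
    pair is flagged significant when |miRES| > ``config.mires_threshold``
    and FDR < ``config.fdr_threshold``. The permutation null of one miRNA is
    shared across its pathways of equal size (the null depends only on the
    ranked weights and the set size). Fully deterministic given
    ``config.seed``; record order is miRNA order × pathway order.
    """
    if len(gene_sets) == 0:
        return []
    _, p_mat, rs_mat = associate_all(mirna, mrna, purity)
    gene_ids = np.asarray(rs_mat.columns)
    n_genes = gene_ids.size
    for name, members in gene_sets:
        overlap = sum(1 for g in members if g in rs_mat.columns)
        if overlap == 0:
            raise ValueError(f"gene set {name!r} has no members in the expression data")
        if overlap >= n_genes:
            raise ValueError(f"gene set {name!r} covers the whole gene universe")

    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(len(rs_mat.index))
    triplets: list[tuple[str, str, float, float]] = []  # mirna, pathway, es, p
    for child, mirna_id in zip(children, rs_mat.index):
        rng = np.random.default_rng(child)
        rs_row = rs_mat.loc[mirna_id].to_numpy()
        order = np.lexsort((gene_ids, -rs_row))
        ranked_ids = gene_ids[order]
        weights = np.abs(rs_row[order]) ** config.weight_exponent
        rank_of = {g: i for i, g in enumerate(ranked_ids)}
        per_set = []
        for name, members in gene_sets:
            pos = np.asarray(sorted(rank_of[g] for g in members if g in rank_of))
            es = float(_es_from_positions(weights, pos[None, :])[0])
            per_set.append((name, pos.size, es))
        # stage 1: shared null per set size
        sizes = sorted({k for _, k, _ in per_set})
        nulls = {k: _null_es(weights, k, config.n_perm, rng) for k in sizes}
        needs_refine = []
        results = {}
        for name, k, es in per_set:
            null = nulls[k]
            if es != 0 and config.n_perm_refine > config.n_perm:
                same = np.sign(null) == np.sign(es)
                exceed = int((same & (np.abs(null) >= abs(es))).sum())
                if exceed <= config.refine_count:
                    needs_refine.append((name, k, es))
            results[name] = (es, _permutation_p(es, null))
        # stage 2: refined null for pairs near the attainable floor
        if needs_refine:
            refined = {
                k: _null_es(weights, k, config.n_perm_refine, rng)
                for k in sorted({k for _, k, _ in needs_refine})
            }
            for name, k, es in needs_refine:
                results[name] = (es, _permutation_p(es, refined[k]))
        for name, _, _ in per_set:
            es, p = results[name]
            triplets.append((mirna_id, name, es, p))

    fdr = bh_fdr([t[3] for t in triplets])
    records = []
    for (mirna_id, pathway, es, p), q in zip(triplets, fdr):
        if es == 0:
            warnings.warn(
                f"enrichment score is exactly 0 for {mirna_id}/{pathway}; "
                "miRES set to 0",
                UserWarning,
                stacklevel=2,
            )
            score = 0.0
        else:
            score = mires(es, p)
        records.append(
            EnrichmentRecord(
                mirna_id=mirna_id,
                pathway=pathway,
                es=es,
                p=p,
                fdr=float(q),
                mires=score,
                significant=bool(
                    abs(score) > config.mires_threshold and q < config.fdr_threshold
                ),
            )
        )
    return records


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate scan records (one row per miRNA–pathway pair)."""
    return pd.DataFrame(
        [
            (r.mirna_id, r.pathway, r.es, r.p, r.fdr, r.mires, r.significant)
            for r in records
        ],
        columns=["mirna_id", "pathway", "es", "p", "fdr", "mires", "significant"],
    )


# ---------------------------------------------------------------------------
# per-sample scoring
# ---------------------------------------------------------------------------


def ssgsea(
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    alpha: float = 0.25,
    rescale: bool = False,
) -> pd.DataFrame:
    """Per-sample gene-set scores (set × sample table).

    Within each sample, genes are ordered by expression (descending, ties by
    gene id) and assigned rank values N..1. The score of a set is the summed
    difference between the weighted in-set ECDF (rank^alpha weights) and the
    uniform out-of-set ECDF over the whole list — the usual single-sample
    enrichment construction for immune-infiltration scoring. ``rescale``
    min–max scales each set's scores to [0, 1] across samples. A set with no
    genes in the matrix scores 0 everywhere, with a warning.
    """
    if expr.state not in ("log2", "tpm"):
        raise ValueError(f"expected state 'log2' or 'tpm', got {expr.state!r}")
    if alpha < 0:
        raise ValueError("alpha must be ≥ 0")
    genes = np.asarray(expr.values.index)
    n_genes = genes.size
    values = expr.values.to_numpy(dtype=float)
    membership = {}
    for name, members in gene_sets:
        mask = np.isin(genes, list(members))
        if not mask.any():
            warnings.warn(
                f"gene set {name!r} has no genes in the matrix; scores set to 0",
                UserWarning,
                stacklevel=2,
            )
        membership[name] = mask

    scores = np.zeros((len(gene_sets), len(expr.sample_ids)))
    rank_values = np.arange(n_genes, 0, -1, dtype=float)  # N..1 down the list
    rank_weights = rank_values**alpha
    for j in range(values.shape[1]):
        order = np.lexsort((genes, -values[:, j]))
        for i, (name, mask) in enumerate(membership.items()):
            in_set = mask[order]
            n_in = int(in_set.sum())
            if n_in == 0 or n_in == n_genes:
                continue
            w_in = np.where(in_set, rank_weights, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_set) / (n_genes - n_in)
            scores[i, j] = np.sum(p_in - p_out)
    table = pd.DataFrame(scores, index=list(membership), columns=expr.sample_ids)
    if rescale:
        rng_ = table.max(axis=1) - table.min(axis=1)
        rng_ = rng_.replace(0, 1.0)
        table = table.sub(table.min(axis=1), axis=0).div(rng_, axis=0)
    return table
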