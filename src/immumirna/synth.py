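"""Synthetic cohort generation with recorded ground truth.

The generator emulates the statistical structure the scan assumes in a bulk
tumour cohort: tumour purity confounds both miRNA and gene expression, a
small number of planted miRNA → pathway regulation effects link a miRNA to a
fraction of a pathway's genes, read counts are Poisson draws around
log-linear means (so the count-level zero filter is exercised), and survival
times follow a Weibull proportional-hazards model driven by a linear risk
score over a few miRNAs.

Generative model, per sample s:

    purity_s            ~ Uniform(purity_low, purity_high)
    mirna log-expr      m_is = μ_i + δ_i·purity_s + ε,        ε ~ N(0, σ²)
    gene  log-expr      g_js = ν_j + b_j·purity_s + γ·z(m_i)_s + ε
                        (the γ term only for target genes of a planted pair,
                         signed by the planted direction)
    counts              ~ Poisson(exp(log-expr))
    true score          u_s = Σ_k c_k · z(m_k)_s   (first miRNAs, coeffs c)
    hazard multiplier   exp(β_surv·u_s + log(hr_step)·1{u_s > cutpoint})
    death time          Weibull(shape, scale) scaled by the multiplier
    censoring           independent Exponential(censor_scale)

All draws derive from a single integer seed; equal seeds give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import (
    ExpressionMatrix,
    GeneSetCollection,
    PurityVector,
    SurvivalData,
    write_expression_table,
    write_gmt,
    write_purity_table,
    write_survival_table,
)

__all__ = [
    "PlantedPair",
    "CohortConfig",
    "CohortTruth",
    "SyntheticCohort",
    "DrugTableConfig",
    "generate_cohort",
    "generate_drug_table",
    "write_cohort",
]


@dataclass(frozen=True)
class PlantedPair:
    """A ground-truth regulation effect: miRNA → fraction of a pathway."""

    mirna_id: str
    pathway: str
    direction: str = "up"  # sign of the planted association
    effect: float = 0.8

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.effect < 0:
            raise ValueError("effect must be ≥ 0")


@dataclass
class CohortConfig:
    """Dimensions and effect sizes of a synthetic cohort.

    Defaults give a mid-sized bulk cohort: 200 samples, 50 miRNAs, 2000
    genes, five 40-gene pathways, moderate purity confounding on both
    feature classes and log-scale noise sd 0.5.
    """

    n_samples: int = 200
    n_mirna: int = 50
    n_genes: int = 2000
    n_pathways: int = 5
    genes_per_pathway: int = 40
    planted: tuple[PlantedPair, ...] = ()
    target_fraction: float = 0.6  # fraction of a pathway's genes that respond
    purity_low: float = 0.3
    purity_high: float = 0.9
    delta: float = 1.0  # purity-confounding magnitude on miRNAs
    b: float = 1.0  # purity-confounding magnitude on genes
    sigma: float = 0.5  # log-scale noise sd
    low_expression_fraction: float = 0.05  # features that are mostly zero
    # survival model
    surv_coefficients: tuple[float, ...] = (0.8, -0.6, 0.4)
    beta_surv: float = 1.0
    hr_step: float = 1.0  # extra hazard ratio above the score cutpoint
    score_cutpoint: float = 0.0
    weibull_shape: float = 1.5
    weibull_scale: float = 5.0
    censor_scale: float = 8.0

    def __post_init__(self) -> None:
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError(
                "pathways require more genes than the universe contains"
            )
        if not (0 < self.target_fraction <= 1):
            raise ValueError("target_fraction must lie in (0, 1]")
        if not (0 <= self.purity_low < self.purity_high <= 1):
            raise ValueError("purity bounds must satisfy 0 ≤ low < high ≤ 1")
        if len(self.surv_coefficients) > self.n_mirna:
            raise ValueError("more survival coefficients than miRNAs")
        mirna_ids = set(_mirna_ids(self.n_mirna))
        pathway_ids = set(_pathway_ids(self.n_pathways))
        for pair in self.planted:
            if pair.mirna_id not in mirna_ids:
                raise ValueError(f"planted miRNA {pair.mirna_id!r} does not exist")
            if pair.pathway not in pathway_ids:
                raise ValueError(f"planted pathway {pair.pathway!r} does not exist")


@dataclass
class CohortTruth:
    """Ground truth recorded at generation time."""

    planted: tuple[PlantedPair, ...]
    target_genes: dict[tuple[str, str], list[str]]
    true_scores: pd.Series
    cutpoint: float


@dataclass
class SyntheticCohort:
    """Expression, purity, pathways and survival for one simulated cohort."""

    mirna_counts: ExpressionMatrix
    mrna_counts: ExpressionMatrix
    purity: PurityVector
    gene_sets: GeneSetCollection
    survival: SurvivalData
    truth: CohortTruth


def _mirna_ids(n: int) -> list[str]:
    return [f"mir_{i + 1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"gene_{i + 1:05d}" for i in range(n)]


def _pathway_ids(n: int) -> list[str]:
    return [f"pathway_{i + 1}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"sample_{i + 1:03d}" for i in range(n)]


def _zscore(rows: np.ndarray) -> np.ndarray:
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (rows - mu) / sd


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Draw one cohort from the generative model; bit-identical per seed."""
    rng = np.random.default_rng(seed)
    samples = _sample_ids(config.n_samples)
    mirnas = _mirna_ids(config.n_mirna)
    genes = _gene_ids(config.n_genes)
    pathways = _pathway_ids(config.n_pathways)

    purity = rng.uniform(config.purity_low, config.purity_high, config.n_samples)

    # miRNA latent log-expression
    mu_m = rng.uniform(3.0, 6.0, config.n_mirna)
    low_m = rng.random(config.n_mirna) < config.low_expression_fraction
    mu_m[low_m] = -1.0  # mostly-zero counts, exercised by the zero filter
    delta_i = rng.uniform(-config.delta, config.delta, config.n_mirna)
    latent_m = (
        mu_m[:, None]
        + delta_i[:, None] * purity[None, :]
        + rng.normal(0.0, config.sigma, (config.n_mirna, config.n_samples))
    )
    z_m = _zscore(latent_m)

    # disjoint pathway membership
    member_idx = rng.choice(
        config.n_genes,
        size=config.n_pathways * config.genes_per_pathway,
        replace=False,
    )
    gene_sets = {}
    pathway_members: dict[str, np.ndarray] = {}
    for i, name in enumerate(pathways):
        block = member_idx[
            i * config.genes_per_pathway : (i + 1) * config.genes_per_pathway
        ]
        pathway_members[name] = block
        gene_sets[name] = frozenset(genes[j] for j in block)

    # gene latent log-expression with purity confounding
    nu_j = rng.uniform(2.0, 6.0, config.n_genes)
    low_g = rng.random(config.n_genes) < config.low_expression_fraction
    nu_j[low_g] = -1.0
    b_j = rng.uniform(-config.b, config.b, config.n_genes)
    latent_g = (
        nu_j[:, None]
        + b_j[:, None] * purity[None, :]
        + rng.normal(0.0, config.sigma, (config.n_genes, config.n_samples))
    )

    # planted regulation: a fraction of the pathway's genes track the miRNA
    target_genes: dict[tuple[str, str], list[str]] = {}
    n_targets = max(1, round(config.target_fraction * config.genes_per_pathway))
    for pair in config.planted:
        members = pathway_members[pair.pathway]
        chosen = rng.choice(members, size=n_targets, replace=False)
        sign = 1.0 if pair.direction == "up" else -1.0
        m_idx = mirnas.index(pair.mirna_id)
        latent_g[chosen, :] += sign * pair.effect * z_m[m_idx][None, :]
        target_genes[(pair.mirna_id, pair.pathway)] = [genes[j] for j in chosen]

    mirna_counts = rng.poisson(np.exp(np.clip(latent_m, None, 20.0)))
    mrna_counts = rng.poisson(np.exp(np.clip(latent_g, None, 20.0)))

    # survival driven by a linear score over the leading miRNAs
    coeffs = np.asarray(config.surv_coefficients, dtype=float)
    true_score = coeffs @ z_m[: coeffs.size]
    lp = config.beta_surv * true_score + np.log(config.hr_step) * (
        true_score > config.score_cutpoint
    )
    u = rng.random(config.n_samples)
    death = config.weibull_scale * (-np.log(u) / np.exp(lp)) ** (
        1.0 / config.weibull_shape
    )
    censor = rng.exponential(config.censor_scale, config.n_samples)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    sample_index = pd.Index(samples, name="sample_id")
    return SyntheticCohort(
        mirna_counts=ExpressionMatrix(
            pd.DataFrame(mirna_counts.astype(float), index=mirnas, columns=samples),
            "counts",
        ),
        mrna_counts=ExpressionMatrix(
            pd.DataFrame(mrna_counts.astype(float), index=genes, columns=samples),
            "counts",
        ),
        purity=PurityVector(pd.Series(purity, index=sample_index, name="purity")),
        gene_sets=GeneSetCollection(gene_sets),
        survival=SurvivalData(
            pd.Series(time, index=sample_index, name="time"),
            pd.Series(event, index=sample_index, name="event"),
        ),
        truth=CohortTruth(
            planted=tuple(config.planted),
            target_genes=target_genes,
            true_scores=pd.Series(true_score, index=sample_index, name="true_score"),
            cutpoint=config.score_cutpoint,
        ),
    )


@dataclass
class DrugTableConfig:
    """Dimensions of a synthetic (log2) IC50 table."""

    n_drugs: int = 20
    n_planted: int = 2
    slope: float = 2.0
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_planted > self.n_drugs:
            raise ValueError("more planted drugs than drugs")


def generate_drug_table(
    config: DrugTableConfig, seed: int, scores: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic drugs × samples log2-IC50 table.

    The first ``n_planted`` drugs are linear in the risk score plus noise;
    the rest are independent standard normal. Returns the table and the
    planted drug ids.
    """
    rng = np.random.default_rng(seed)
    drug_ids = [f"drug_{i + 1:02d}" for i in range(config.n_drugs)]
    score_vec = scores.to_numpy(dtype=float)
    table = rng.normal(0.0, 1.0, (config.n_drugs, score_vec.size))
    for i in range(config.n_planted):
        table[i] = config.slope * score_vec + rng.normal(
            0.0, config.noise_sd, score_vec.size
        )
    frame = pd.DataFrame(table, index=pd.Index(drug_ids, name="drug_id"),
                         columns=scores.index)
    return frame, drug_ids[: config.n_planted]


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write the cohort as the pipeline's standard input files plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": outdir / "mirna_counts.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "purity": outdir / "purity.tsv",
        "gene_sets": outdir / "pathways.gmt",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_table(cohort.mirna_counts, paths["mirna_counts"])
    write_expression_table(cohort.mrna_counts, paths["mrna_counts"])
    write_purity_table(cohort.purity, paths["purity"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    write_survival_table(cohort.survival, paths["survival"])
    with open(paths["truth"], "w") as handle:
        handle.write(f"# score_cutpoint={cohort.truth.cutpoint:g}\n")
        handle.write("mirna_id\tpathway\tdirection\teffect\tn_target_genes\n")
        for pair in cohort.truth.planted:
            targets = cohort.truth.target_genes[(pair.mirna_id, pair.pathway)]
            handle.write(
                f"{pair.mirna_id}\t{pair.pathway}\t{pair.direction}\t"
                f"{pair.effect:g}\t{len(targets)}\n"
            )
    return paths
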