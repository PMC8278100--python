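# immumirna

Tools for finding miRNA regulators of immune-associated pathways in bulk
tumour expression data, and for applying a three-miRNA prognostic risk
signature — written for computational biologists working with matched
miRNA/mRNA cohorts (e.g. colorectal cancer) who need purity-aware
regulator inference and survival stratification without any external
downloads: every stage can be exercised on synthetic cohorts with known
ground truth.

## The method

Tumour purity confounds miRNA–gene co-expression, so for miRNA *i* and
gene *j* the association is the first-order partial correlation
controlling purity *P*:

    PCC(ij) = (R_MG − R_MP·R_GP) / (√(1 − R_MP²) · √(1 − R_GP²))

with a t-test p-value on n−3 degrees of freedom. Genes are ranked by the
rank score `RS(ij) = −log10(P(ij)) × sign(PCC(ij))` and each immune
pathway is scored on that ranking by a weighted Kolmogorov–Smirnov running
sum (enrichment score ES). A gene-set permutation test gives p, and

    miRES = 1 − 2p   (ES > 0)
            2p − 1   (ES < 0)

combines both into a score in [−1, 1]. Pairs with |miRES| > 0.995 and
Benjamini–Hochberg FDR < 0.05 across all scanned pairs are called
significant.

Downstream, the packaged IAMIPS signature scores a patient as

    Risk = 0.015·z(miR-216a-5p) − 0.035·z(miR-194-3p) − 0.124·z(miR-3677-3p)

on per-cohort z-scored expression, splitting at the packaged cutoff 0.05
(or at a cutpoint re-derived by the maximally selected log-rank statistic).
The package also provides per-sample pathway scoring (ssGSEA-style) and a
dual-criterion drug screen on log2 IC50 tables (|r| > 0.3 and
|log2FC| > 0.5, both at FDR < 0.05).

## Worked example

`examples/01_scan_for_regulators.py` builds a 120-sample synthetic cohort
with one planted regulator (mir_001 driving pathway_1 through 60% of its
genes at effect 0.8), runs the full scan and prints the top pairs:

```
mirna_id   pathway      es         p    fdr   mires  significant
 mir_001 pathway_1  0.9377 0.0002917  0.014  0.9994         True
 mir_011 pathway_4  0.6091   0.01517 0.3641  0.9697        False
 mir_003 pathway_4 -0.5186   0.04733 0.5688 -0.9053        False
 mir_010 pathway_1 -0.5339   0.05273 0.5688 -0.8945        False
 mir_006 pathway_4 -0.5305   0.05925 0.5688 -0.8815        False
```

The planted pair tops the table: its pathway genes crowd the top of the
miRNA's purity-adjusted ranking (ES 0.94), essentially no random gene set
matches that (p ≈ 3·10⁻⁴, hence miRES 0.9994 > 0.995) and it alone
survives the FDR filter. The other examples cover the risk score and
cutpoint search (`02`), per-sample pathway scores (`03`) and the drug
screen (`04`).

The same pipeline is available from the shell:

```sh
immumirna simulate --out-dir cohort --seed 7 --plant mir_001:pathway_1:up:0.8
immumirna scan --mirna cohort/mirna_counts.tsv --mrna cohort/mrna_counts.tsv \
    --purity cohort/purity.tsv --gene-sets cohort/pathways.gmt \
    --seed 1 --out scan.tsv
```

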