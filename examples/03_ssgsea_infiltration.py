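"""Per-sample pathway scores (ssGSEA-style) on a synthetic cohort.

Scores each pathway in each sample and shows that samples differ in their
pathway activity; on real data the sets would be immune-cell signatures and
the scores read as relative infiltration.
"""

import immumirna as im

cohort = im.generate_cohort(
    im.CohortConfig(n_samples=6, n_mirna=5, n_genes=300, n_pathways=3,
                    genes_per_pathway=25),
    seed=3,
)
expr = im.log2p1(im.rpm_normalize(im.filter_zero_fraction(cohort.mrna_counts)))
table = im.ssgsea(expr, cohort.gene_sets, alpha=0.25)
print(table.round(2).to_string())
# Rows are gene sets, columns samples; larger scores mean the set's genes
# sit higher in that sample's expression ranking.
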