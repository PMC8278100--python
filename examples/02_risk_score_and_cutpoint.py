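"""Apply a linear miRNA risk signature and find a survival cutpoint.

Shows both faces of the signature module: the packaged three-miRNA
signature on a toy z-scored matrix, and a survival-optimal cutpoint search
on a synthetic cohort whose hazard follows a score.
"""

import numpy as np
import pandas as pd

import immumirna as im

# 1) the packaged signature on a tiny z-scored matrix
model = im.load_iamips()
z = im.ExpressionMatrix(
    pd.DataFrame(
        [[1.0, 0.0, -1.0],   # miR-216a-5p
         [0.0, 1.0, -1.0],   # miR-194-3p
         [0.0, 0.0, 2.0]],   # miR-3677-3p
        index=model.mirna_ids, columns=["patient_a", "patient_b", "patient_c"],
    ),
    "zscore",
)
scores = im.risk_score(z, model)
profile = im.assign_groups(scores, model.cutoff)
print(profile.to_string())
# score is the coefficient-weighted sum of z-scored expression; a score
# strictly above the packaged cutoff 0.05 puts the patient in the
# high-risk group.

# 2) cutpoint recovery on a synthetic cohort with a step hazard at 0
cohort = im.generate_cohort(
    im.CohortConfig(n_samples=300, hr_step=3.0, beta_surv=0.0), seed=11
)
cut = im.optimal_cutpoint(cohort.truth.true_scores, cohort.survival)
groups = im.assign_groups(cohort.truth.true_scores, cut)["group"]
chi2, p = im.log_rank_statistic(cohort.survival, groups)
print(f"\nrecovered cutpoint {cut:+.3f} (truth {cohort.truth.cutpoint:+.3f}); "
      f"log-rank chi2 {chi2:.1f}, p {p:.2e}")
# The maximally selected log-rank search should land near the true step
# location, and the split should separate survival strongly.
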