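"""Screen a log2-IC50 drug table against the risk score.

Plants one drug whose IC50 tracks the score among 19 independent drugs and
shows that the dual criterion (|r| > 0.3 & FDR < 0.05, |log2FC| > 0.5 &
FDR < 0.05) singles it out.
"""

import numpy as np
import pandas as pd

import immumirna as im

rng = np.random.default_rng(5)
samples = pd.Index([f"s{i}" for i in range(80)], name="sample_id")
scores = pd.Series(rng.normal(size=80), index=samples, name="risk_score")
groups = im.assign_groups(scores, float(scores.median()))["group"]

table, planted = im.generate_drug_table(
    im.DrugTableConfig(n_drugs=20, n_planted=1), seed=9, scores=scores
)
result = im.drug_screen(table, scores, groups)
print(result[result.selected | (result.drug_id.isin(planted))]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\nplanted: {planted}; selected: {result.loc[result.selected, 'drug_id'].tolist()}")
# A positive r means higher IC50 (less sensitivity) with higher risk:
# low-risk patients would be the sensitive group for such a drug.
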