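"""Kruskal-Wallis eQTL tests and random-forest validation.

Tests each planted (transcript, variant) pair for genotype-dependent
expression in all biopsies and per tissue stratum, then validates the
planted transcript set as a response classifier with out-of-bag ROC.
"""

import numpy as np

from isogx import eqtl
from isogx.simulate import CohortDesign, generate_cohort

cohort = generate_cohort(CohortDesign(seed=1))
res = eqtl.eqtl_scan(
    cohort.truth.eqtl_pairs, cohort.expression, cohort.genotypes, cohort.sample_meta
)
print(res.round(4).to_string(index=False))

feats = np.log2(
    cohort.expression.tpm.loc[cohort.truth.planted_dei["transcript_id"][:8]].T + 1.0
)
feats["tissue_state"] = (cohort.sample_meta["tissue_state"] == "inflamed").astype(float)
val = eqtl.random_forest_validate(
    feats, cohort.sample_meta["response"].astype(int), seed=1, mode="oob"
)
print(f"\nOOB AUC of planted-transcript classifier: {val.auc:.3f} "
      f"(CI95 {val.ci_low:.3f}-{val.ci_high:.3f})")
# eQTL p-values come from the tie-corrected H statistic over dosage groups
# {0,1,2}; at n = 22 the test is deliberately conservative. OOB AUC is the
# honest internal estimate — in-sample AUC at this n is near 1 by design.
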