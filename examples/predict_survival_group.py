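"""Random-forest survival-group prediction: TNM staging vs Combined.

Labels each LCC patient short/long survivor (below/at-or-above the median
imputed survival), then compares 10-fold cross-validated AUC of a
500-tree forest using clinical staging only (age, T, N, M, stage) against
the same baseline combined with the 24 radiomic features, on identical
folds.  Finishes with out-of-bag permutation importance.
"""

import numpy as np

from radsurv import (
    FEATURE_NAMES,
    SimulationConfig,
    compare_feature_sets,
    make_labels,
    oob_importance,
    select_group,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(n_patients=277, seed=1))
lcc = select_group(cohort, "subtype", "LCC")

reports = compare_feature_sets(lcc, list(FEATURE_NAMES), n_trees=500, n_folds=10, seed=0)
for name, rep in reports.items():
    print(f"{name:9s} mean AUC = {rep.mean_auc:.3f}  (n={rep.n}, 10 folds)")
print("\nA Combined > TNM gap means tumor texture/shape carries prognostic"
      "\ninformation beyond clinical staging in this subgroup.\n")

y, _ = make_labels(lcc)
importance = oob_importance(
    lcc[list(FEATURE_NAMES)].to_numpy(float), y,
    feature_names=list(FEATURE_NAMES), n_trees=500, n_folds=10, seed=0,
)
print("top 5 features by normalized OOB permutation importance:")
print(importance.head(5).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
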