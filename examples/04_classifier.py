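"""Random-forest discrimination of suicide attempters from controls.

Simulates a two-group cohort, quantifies editing features, splits 2/3 train /
1/3 test (stratified), selects significant features on the training set only,
fits a 1000-tree forest with 2 candidate features per split, and prints the
held-out diagnostic performance.
"""

from edisle import (
    ClassifierConfig,
    CohortConfig,
    filter_analysis_set,
    run_classifier,
    simulate_cohort,
)
from edisle.pipeline import quantify_cohort

cfg = CohortConfig(n_ctrl=45, n_dep=0, n_sa=40, reads_per_replicate=2_000, seed=4)
cohort = simulate_cohort(cfg)
q = quantify_cohort(cohort)
records, _ = filter_analysis_set(q["features"].reset_index())

feat_cols = [c for c in records.columns if c.startswith(("site_", "iso_"))]
rep = run_classifier(records, feat_cols, ClassifierConfig(trees=1000, seed=4))

lo, hi = rep.auc_ci
print(f"train n = {rep.n_train}, test n = {rep.n_test}")
print(f"selected features: {', '.join(rep.features)}")
print(f"held-out AUC = {rep.auc:.3f} [{lo:.3f}; {hi:.3f}]")
print(f"operating point (max Youden): sensitivity = {rep.sensitivity:.2f}, "
      f"specificity = {rep.specificity:.2f}")

top = sorted(rep.importances.items(), key=lambda kv: -kv[1])[:3]
print("top importances: " + ", ".join(f"{k} = {v:.2f}" for k, v in top))

# AUC is the probability a random attempter scores above a random control;
# the bootstrap interval reflects the finite held-out set.  With the shipped
# group effect the dominant site and the non-edited pattern carry most of
# the signal.
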