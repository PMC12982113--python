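"""Simulate a clinical cohort and run the group statistics.

A cohort of 19 controls and 41 patients (14 planted responders) is drawn;
the script tests the planted pre/post clinical improvements and the planted
transition-probability changes, printing adjusted p-values.
"""

import numpy as np

from easleep.groupstats import clinical_change_tests, results_table, transition_tests
from easleep.microstates import CLASSES
from easleep.synthgen import CohortSpec, simulate_cohort

cohort = simulate_cohort(CohortSpec(n_hc=19, n_ci=41, n_responders=14, seed=7))
table = cohort.table
print(f"cohort: {len(table)} subjects "
      f"({(table['group'] == 'HC').sum()} HC, {(table['group'] == 'CI').sum()} CI)")

clin = clinical_change_tests(table)
print("\nclinical scales, patients pre vs post treatment:")
print(results_table(clin)[["effect", "test", "statistic", "p_raw"]].to_string(index=False))

ci = table[table["group"] == "CI"].sort_values("subject_id")
def stack(frame):
    mats = np.zeros((len(frame), 4, 4))
    for i, a in enumerate(CLASSES):
        for j, b in enumerate(CLASSES):
            if i != j:
                mats[:, i, j] = frame[f"OrgTM_{a}->{b}"].to_numpy()
    return mats

pre = stack(ci)
post = stack(cohort.metrics_post.loc[ci["subject_id"]])
trans = transition_tests(pre, post, paired=True)
flagged = [r for r in trans if r.p_adjusted < 0.05]
print(f"\ntransition tests (family 12): {len(flagged)} of 12 significant after "
      "Bonferroni; planted responder reversals drive the flagged pairs:")
for r in flagged:
    print(f"  {r.effect_name}: adjusted p = {r.p_adjusted:.2g}")
print("\nLow p-values on the clinical scales reflect the planted treatment "
      "effect; non-flagged transitions behave as nulls.")
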