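"""Screen two cohorts for distribution shift, feature by feature.

Emulates a training hospital and an external-validation hospital whose first
five features drifted, then runs the per-feature Mann-Whitney U screen with
Bonferroni correction — the standard check before trusting external
validation numbers.
"""

import numpy as np

from kdeknn import FixtureSpec, make_shifted_pair, shift_report

spec = FixtureSpec(n_negative=600, n_positive=250, d=10, correlation=0.0,
                   missing_rate=0.05, seed=3)
shift = np.zeros(10)
shift[:5] = 1.5  # the first five features drift between hospitals

cohort_a, cohort_b = make_shifted_pair(spec, shift=shift)
table = shift_report(cohort_a.values, cohort_b.values, cohort_a.feature_names)
print(table.to_string(index=False))
n_sig = int(table["significant"].sum())
print(f"{n_sig} of {len(table)} features flagged at Bonferroni-adjusted "
      "p < 0.01 — exactly the drifted ones should appear")
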