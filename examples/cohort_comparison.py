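"""Simulate a benign/malignant cohort and compare perfusion indicators.

Generates the default 52/74 benign/malignant cohort (gamma-variate bolus
parameters drawn log-normally around group means, noisy sampled curves),
quantifies every subject's curve, and runs Welch tests per indicator.
A negative direction means the malignant group's mean is higher.
"""

from ceuskit import compare_groups, comparisons_table, generate_cohort, quantify_batch
from ceuskit.synthetic import default_bile_duct_cohort

records = generate_cohort(default_bile_duct_cohort(seed=11))
table = quantify_batch([r.curve for r in records])
table["group"] = [r.group_label for r in records]

comparisons = []
for parameter in ("TTP", "AUC", "Grad", "I_max"):
    comparisons.extend(compare_groups(table, parameter))
out = comparisons_table(comparisons)
print(out[["parameter", "mean1", "mean2", "statistic", "p_value", "direction"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    "\nmean1 = benign, mean2 = malignant: the malignant group peaks earlier"
    " (lower TTP) with larger AUC, steeper wash-in and higher I_max."
)
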