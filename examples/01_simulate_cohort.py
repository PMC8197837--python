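"""Simulate a paper-scale COPD monitoring cohort and inspect its structure.

43 daily records of one monitored subject: 10 correlated vital-sign
predictors plus PEF, with the binary class cut at PEF = 400 L/min.
"""

import numpy as np

import vitalgan as vg

cohort = vg.generate_cohort(43, seed=7)
print(f"records: {cohort.n}, classes: {cohort.class_counts()}")

for name in ("fev1", "heart_rate", "map"):
    hi = cohort.subset_class("high").column(name).mean()
    lo = cohort.subset_class("low").column(name).mean()
    print(f"  {name:12s} mean  high={hi:7.2f}  low={lo:7.2f}")

r = np.corrcoef(cohort.column("fev1"), cohort.pef)[0, 1]
print(f"fev1-pef correlation: {r:.2f}")

vg.write_dataset(cohort, "cohort.csv")
print("wrote cohort.csv")

# The class-high subset (good breathing performance, PEF >= 400) shows
# higher FEV1/MAP and lower resting heart rate — the structure every
# downstream stage (GAN, metrics, rules) is expected to preserve.
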