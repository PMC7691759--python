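"""Classify trials into yield environments by exact 1-D k-means.

Trial mean yields cluster into low- (LYE), medium- (MYE) and
high-yielding (HYE) environments; the high class is excluded from the
gain analysis.  The solver is an exact dynamic program, so the
partition is the global optimum and needs no random restarts.
"""

import numpy as np

from metgains import classify_environments
from metgains.single_trial import TrialSummary

import pandas as pd

rng = np.random.default_rng(0)
means = np.concatenate([rng.normal(2.4, 0.3, 12), rng.normal(4.6, 0.3, 12),
                        rng.normal(6.5, 0.2, 3)])
summaries = [
    TrialSummary(f"T{i:02d}", 0, m, 0.1, 0.0, 0.1, 0.8, pd.Series(dtype=float))
    for i, m in enumerate(means)
]

assignments = classify_environments(summaries)
centers = {}
counts = {}
for a in assignments:
    centers[a.class_label] = a.cluster_center
    counts[a.class_label] = counts.get(a.class_label, 0) + 1

for cls in ("LYE", "MYE", "HYE"):
    print(f"{cls}: {counts[cls]:2d} trials, center {centers[cls]:.2f} t/ha")
print()
print("LYE/MYE centers near 2.4 and 4.6 t/ha mirror the yield levels the "
      "generator injects; HYE trials are dropped downstream.")
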