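"""Benchmark support recovery with penalty-swept ROC curves.

Sweeps the l1 penalty to trace a ROC curve for recovering each planted
support, then compares the sweep against a plain-SVD loading ranking and
a random-score baseline over several simulations.
"""

import numpy as np

from jammit import SimulationConfig, compare_over_sims
from jammit.evaluation import RandomScoreDetector, SvdThresholdDetector

cfg = SimulationConfig(p_choices=(1000,), n=50, snr_db=0.0)
res = compare_over_sims(
    cfg, [SvdThresholdDetector(), RandomScoreDetector(seed=1)],
    n_sims=10, seed=3, L=20,
)

med = res.table.groupby(["detector", "signal"])["auroc"].median()
print("median AUROC per detector and planted signal:")
print(med.to_string())
print("\ndelta AUROC (sweep minus baseline), median and exact sign-test p:")
for (det, sig), d in res.deltas.items():
    print(f"  vs {det:14s} {sig:4s}: median {np.median(d):+.4f}  p={res.sign_p[(det, sig)]:.4f}")
print(
    "-> positive deltas mean the sparse sweep ranked true support rows above\n"
    "   noise rows more reliably than the baseline on the same simulations"
)
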