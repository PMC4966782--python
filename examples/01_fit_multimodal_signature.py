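"""Fit a sparse multi-modal signature on simulated two-block data.

Builds a small two-type MMDS with a planted step signal, stacks and
scales it, fits the sparse rank-1 model at a moderate penalty and prints
the signature parsed per data type.
"""

import numpy as np

from jammit import (
    SimulationConfig,
    extract_signature,
    jammit_fit,
    lambda_grid,
    simulate_mmds,
)

sim = simulate_mmds(SimulationConfig(p_choices=(1000,), n=50, snr_db=0.0, seed=42))
sm = sim.supermatrix()
print(f"super-matrix: p={sm.p} rows ({len(sm.block_map)} data types), n={sm.n} samples")

grid = lambda_grid(sm, 25)
lam = grid.lambdas[2]  # a small penalty well inside (0, lam_sup)
fit = jammit_fit(sm, lam)
sig = extract_signature(fit, sm)

print(f"penalty lam={lam:.4f} (lam_sup={grid.lam_sup:.4f})")
print(f"signature size s={fit.s}, per type: {sig.per_block_counts}")
corr = max(
    abs(np.corrcoef(fit.v, s)[0, 1]) for s in sim.signals.values()
)
print(f"|corr(eigen-signal, best planted signal)| = {corr:.3f}")
print(
    "-> the non-zero eigen-array entries name the variables, in every data type,\n"
    "   that jointly explain one per-sample signal shared across the types"
)
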