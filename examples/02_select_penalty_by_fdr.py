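"""Choose the l1 penalty by permutation FDR.

Estimates the joint and per-type FDR profiles over a penalty grid on
planted-signal data and on pure noise, and shows that a significant
penalty is only found when a shared signal is actually present.
"""

import numpy as np

from jammit import (
    DataMatrix,
    SimulationConfig,
    estimate_fdr,
    frobenius_scale,
    lambda_grid,
    select_lambda,
    simulate_mmds,
    stack,
)

# planted-signal data
sim = simulate_mmds(SimulationConfig(p_choices=(1000,), n=50, snr_db=0.0, seed=1))
sm = sim.supermatrix()
grid = lambda_grid(sm, 25)
prof = estimate_fdr(sm, grid, B=20, seed=1)
lam_star = select_lambda(prof, threshold=0.05, mode="largest_signature")
print("planted signal:")
print(f"  min FDR over grid = {prof.fdr_joint.min():.4f}")
print(f"  lam* = {lam_star:.4f}, observed signature size there = "
      f"{prof.s_obs[np.searchsorted(grid.lambdas, lam_star)]}")

# pure noise
rng = np.random.default_rng(2)
noise = DataMatrix(
    rng.standard_normal((1000, 50)),
    [f"v{i}" for i in range(1000)],
    [f"s{j}" for j in range(50)],
    "noise",
)
smn = frobenius_scale(stack([noise]))
prof_n = estimate_fdr(smn, lambda_grid(smn, 25), B=20, seed=2)
print("pure noise:")
print(f"  mean FDR over grid = {prof_n.fdr_joint.mean():.3f}")
print(f"  selection -> {select_lambda(prof_n, 0.05)}")
print(
    "-> row-permutation nulls calibrate signature size: with a real shared\n"
    "   signal FDR collapses and a lam* is accepted; on noise it never does"
)
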