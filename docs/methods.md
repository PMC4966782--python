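# Methods

## The model

A multi-modal data set (MMDS) is a collection of K preprocessed
variables-by-samples matrices D_1, ..., D_K (p_k × n, shared ordered
sample columns).  Vertically stacking them gives the p × n super-matrix
D (p = Σ p_k), scaled to unit Frobenius norm so that no single data type
dominates through size or dynamic range.  The method approximates D by a
rank-1 outer product

    D ≈ u vᵀ,     v = Dᵀ u,

minimizing  E(u, v, λ) = ‖D − u vᵀ‖²_F + λ‖u‖₁.

The left factor u (the *eigen-array*) holds one loading per stacked
variable; the ℓ1 penalty drives most loadings to exact zero, and the
surviving variables form a multi-modal *signature* that can be parsed
per data type by the stacking order.  The right factor v (the
*eigen-signal*) is a dense per-sample signal shared by all data types —
the biological or clinical attribute the signature explains.  At λ = 0
the solution is the classical best rank-1 SVD approximation; at
λ ≥ λ_sup = 2·max_i |d_i·v₀| (v₀ the unit leading right singular
vector) the signature is empty.

### Solver

`jammit_fit` alternates two exact coordinate updates from the SVD
initialization:

1. u-update (closed form, separable per row): with z_i = d_i·v,
   u_i = sign(z_i)·max(|z_i| − λ/2, 0)/‖v‖² — soft-thresholding, the
   exact minimizer of E for fixed v;
2. v-update: v ← Dᵀu, then rescaled to unit ℓ2 norm, which is the exact
   minimizer of E over the unit sphere for fixed u.

Both updates are exact coordinate minimizations, so the objective
evaluated after each u-update is non-increasing; the loop stops when the
relative ℓ2 change of both factors falls below `tol` (default 1e-6,
`max_iter` 500 — convergence typically takes a handful of iterations).
If u becomes all-zero the fit returns immediately as empty.

Numerical conventions:

* **Scale.** Keeping v at unit norm inside the loop pins the threshold
  λ/2 to a fixed scale (consistent with the λ_sup definition above) and
  avoids the two-cycle scale oscillation of the fully coupled updates.
  On exit u is normalized to unit ℓ2 norm and v recomputed as Dᵀu, so
  the returned pair honors the constraint with a scale-consistent outer
  product (at λ = 0 it equals the SVD truncation u₁σ₁v₁ᵀ exactly).
* **Sign.** The largest-magnitude entry of u is made positive (the SVD
  sign is arbitrary).
* **Debiasing (default on).** Soft-thresholding shrinks every selected
  weight by ~λ/2.  Deflating the *penalized* outer product therefore
  leaves a coherent rank-1 remnant spread over the signature rows, which
  re-triggers detection on later iterations and fragments one real
  signal into several partial ones (observed directly in simulation).
  `jammit_fit` consequently refits the selected support by unpenalized
  least squares against the final eigen-signal before returning
  (select-then-refit, as in the relaxed LASSO).  The support, the λ = 0
  behavior, the objective trace and the v = Dᵀu contract are unchanged;
  pass `debias=False` for the raw penalized factors.
* λ is interpreted on the Frobenius-scaled super-matrix; a single λ is
  shared by all blocks (no per-block penalty weighting).

## Choosing λ by permutation FDR

Real data carry no ground truth, so λ is calibrated against a
permutation null: every row of the super-matrix is shuffled
independently (`numpy` `Generator.permuted(axis=1)`), destroying the
shared column signal while preserving each row's marginal distribution.
For a grid Λ of L penalties from 0 to λ_sup (linear by default;
geometric spacing optional) and B null replicates,

    FDR(λ) = mean_b min(1, s_null_b(λ) / s_obs(λ)),

with FDR ≡ 1 wherever the observed signature is empty; a median
aggregator is available behind a flag.  Per-type profiles restrict both
counts to one block's rows: a genuine *shared* signal drives all
per-type profiles down in unison, whereas variation unique to one data
type depresses only that block's profile.  Defaults: L = 50, B = 100;
FDR estimates are bit-reproducible for a fixed seed.

`select_lambda` offers two documented rules:

* `"min_fdr"` (default): among local minima of the joint profile
  (endpoints eligible, a plateau counted once at its largest-λ point)
  at or below the threshold, take the smallest FDR, ties toward the
  larger penalty.
* `"largest_signature"`: the smallest λ whose FDR is at or below the
  threshold with a non-empty signature.  On planted-signal data the
  profile decays monotonically to ~0, so the literal minimum sits at the
  extreme-sparsity tail where the fit explains almost nothing; the first
  crossing instead captures the full supported set.  This is the rule
  the multi-signal iteration uses, and it mirrors how significant
  penalties with large signatures are chosen in practice.

## Sequential extraction (deflation)

Stronger signals mask weaker ones.  `jammit_iterate` loops
{grid → FDR profile → λ* → fit → record → deflate (D′ = D − u vᵀ)} on
the running residual and stops when no λ qualifies, a fit is empty, or
the iteration count reaches R* = min_k rank(D_k).  The FDR profile is
re-estimated on every residual; each per-iteration permutation seed is
derived from the run seed via `SeedSequence.spawn`.  The stack is scaled
once up front; residuals are not re-scaled (the grid is recomputed from
each residual and the problem is scale-equivariant, so re-scaling would
change nothing, while keeping one fixed matrix makes the reported
residual-norm fractions exact).

Leave-one-sample-out robustness (`loocv_signatures`) refits at a fixed λ
with each sample withheld and reports per-fold recapitulation of the
full-data signature plus the all-fold intersection signature.

## Synthetic data

`simulate_mmds` emulates the two-block study design: block sizes drawn
from {1000, 2000, ..., 10000}, n = 50 shared samples, and two planted
per-sample signals — a ±1 step over the first/last 25 samples
(differential-expression surrogate) and a standardized Gaussian random
signal (an unmeasured sample attribute) — each carried by a disjoint 2%
of rows per block (floor of 20 rows).  Supported rows hold amplitude ×
signal with amplitudes uniform on [0.5, 1.5] and random sign; noise is
i.i.d. N(0, 1) (Student-t, df 5, behind a flag).  The stacked signal
matrix is rescaled so the realized SNR
(10·log10 of the variance ratio of the vectorized signal and noise
matrices) hits the target exactly; blocks are returned row-centered.
Ground truth (supports, signals, realized SNR) is emitted with the data
and never recomputed downstream.  An `orthogonalize_signals` flag
projects the random signal exactly orthogonal to the step (used when a
clean two-iteration deflation is the property of interest); by default
the two are only uncorrelated in expectation.

What the generator does *not* emulate: heteroscedastic per-variable
noise, correlated variables (co-regulation, probe cross-talk), batch
effects, heavy-tailed or missing entries, and platform-specific
intensity distributions.  Passing tests on these simulations therefore
demonstrates correctness of the machinery and detection behavior under
the stated design, not performance on any particular real platform.

## Support-recovery evaluation

Sweeping λ over the grid shrinks the detected set from all rows (λ = 0)
to none (λ_sup); scoring each detected set against the planted support
traces a ROC curve, integrated by trapezoid over FPR-sorted points
augmented with (0,0) and (1,1), duplicates removed.  With two planted
signals, one deflation iteration is matched to each signal by the larger
|correlation| of its eigen-signal with the planted signal; each sweep is
run on the matched (residual) matrix.  The pluggable detector interface
accepts any method producing per-row scores (scored by AUROC via
scikit-learn) or λ-indexed detected sets; bundled baselines are the
plain-SVD |loading| ranking and an i.i.d. random score.  Paired
per-simulation AUROC differences (ΔAUROC, positive favoring the first
detector) are tested with the exact two-sided binomial sign test on
non-zero signs.

## Eigen-survival model

Given a signature's row-centered realization ζ(D) (s × n), the ESM is
its unit-norm leading left singular vector, sign-fixed like the
eigen-array; a patient's prognostic score is the inner product of the
loadings with their profile.  Scores project unchanged onto an
independent cohort's realization of the same variables (rows matched by
ID).  Patients are stratified by extreme quartiles of size floor(m/4)
(291 → 72 + 72, 99 → 24 + 24), boundary ties broken by stable sample
order; the grouping is invariant to shifting or positively rescaling the
scores.  Separation is tested by the two-group log-rank test (chi-square,
1 df) and by Cox proportional hazards (Efron ties, Wald p-values), both
via lifelines; censoring is coded 1 = censored throughout and converted
internally to events.  A signature is called *predictive* only when both
tests reach p ≤ 0.05.  The loading sign convention is mathematical, not
prognostic: whether a high score is favorable is read off the
hazard-ratio sign.

## Problem sizes used by the test suite and acceptance script

SVD-limit and soft-threshold oracle checks use 20 random 200×30 and 50
random 20×10 matrices (oracle: per-coordinate grid minimization, step
1e-4).  Support-recovery AUROC and FDR calibration use the two-block
design at p_k = 1000, n = 50, SNR 0 dB (10 and 5 seeds; B = 20
permutations, L = 25); the pure-noise null uses 500×30 matrices.
Two-signal deflation uses 3 seeds with orthogonalized signals.  Survival
checks use 50 synthetic cohorts of n = 300 with a hazard ratio of 2 per
score SD and ~25% administrative censoring, plus 500 null replicates at
n = 60 for the type-I rate.  These sizes were chosen as the smallest
designs at which the studied behaviors are stable across seeds.

## Known limitations

* The row-permutation null preserves row marginals but not inter-row
  correlation; on strongly co-regulated data the null signature sizes
  can be optimistic, making FDR estimates liberal.
* The FDR grid search refits (B+1)·L models per iteration; B = 100 on a
  20k-row stack is minutes of compute, and the cost is linear in all of
  B, L and p.
* Deflation assumes signals of interest are well approximated by
  successive rank-1 terms with distinct eigen-signals; two signals with
  nearly collinear eigen-signals are extracted as one.
* `quantile_normalize` uses the average-rank tie convention; columns
  with many ties will not match the reference distribution exactly.
* The iteration bound R* uses numpy's numerical rank of each block,
  which on noisy data nearly always equals min(p_k, n); it is a
  safeguard, not a practical stopping rule — the FDR threshold is.
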