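# jammit

Joint analysis of multiple high-dimensional omics matrices by sparse
rank-1 matrix approximation.

## The problem

Multi-modal studies measure several data types — mRNA, microRNA, DNA
methylation, imaging-derived covariates — on one common set of samples,
each yielding a tall variables-by-samples matrix (p ≫ n).  The
biological signal of interest is usually carried by a small fraction of
the measured variables, buried in noise, and shared *across* the data
types.  This package finds those variables jointly: it stacks the
preprocessed matrices into one super-matrix D (scaled to unit Frobenius
norm) and fits the sparse rank-1 approximation

    D ≈ u vᵀ,  v = Dᵀu,  minimizing  ‖D − u vᵀ‖²_F + λ‖u‖₁ ,

where the eigen-array u holds per-variable loadings driven to exact
zeros by the ℓ1 penalty and the eigen-signal v is a dense per-sample
signal shared by all data types.  The non-zero entries of u define a
multi-modal signature, parsed per data type by stacking order.  The
penalty λ is selected by permutation-estimated false discovery rate
(each row of D shuffled independently); additional signals are
extracted sequentially by deflating the fitted component (D′ = D − u vᵀ)
and repeating.  Signatures can be carried into an eigen-survival model
(the leading left singular vector of the signature's realization) whose
per-patient scores stratify survival by extreme quartiles, tested by
log-rank and Cox models.

Audience: computational biologists integrating multi-omics matrices who
want sparse, cross-type signatures with permutation-calibrated size, and
a simulation/evaluation harness to validate detection performance.

## Worked example

`examples/03_sequential_signal_extraction.py` plants two sparsely
supported signals (a 25-vs-25 step and an orthogonal random signal, 20
rows per signal per 1000-row block, SNR 0 dB) in a two-type data set and
runs the full grid → FDR → fit → deflate loop:

```
iterations accepted: 2 (bound R* = 49)
stop reason: no significant lambda
  iteration 1: lam*=0.0770, s=40, matches 'rand' signal (support Jaccard 1.00), residual norm fraction 0.862
  iteration 2: lam*=0.0702, s=40, matches 'step' signal (support Jaccard 1.00), residual norm fraction 0.701
```

Each iteration selected its penalty from a fresh permutation-FDR profile
(B = 20 nulls, 25-point grid), recovered one planted signature exactly
(all 40 supported rows, no false variables — Jaccard 1.00), subtracted
the fitted rank-1 component, and the third pass found nothing
significant and stopped.  The other scripts in `examples/` demonstrate
single fits (`01`), FDR-based penalty selection on signal vs pure noise
(`02`), ROC/AUROC benchmarking against baseline detectors (`04`) and
eigen-survival modeling with projection onto an independent cohort
(`05`); each prints a closing note explaining the numbers.

A thin CLI mirrors the library for shell use
(`jammit simulate|fit|fdr|iterate|evaluate|survival`, see
`jammit --help`); identical inputs and seed reproduce outputs byte for
byte.

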