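"""Penalty selection and sequential signal extraction.

The l1 penalty ``lam`` controls signature size: ``lam = 0`` keeps every
variable (the plain SVD) while ``lam >= lam_sup`` empties the signature.
Because no ground truth exists for real data, ``lam`` is chosen by a
permutation estimate of the false discovery rate (FDR): each row of the
super-matrix is shuffled independently, destroying the shared column
signal while preserving row marginals, and the signature sizes obtained
on permuted data calibrate how many of the observed selections could be
chance.  A ``lam*`` is accepted when the FDR profile has a local minimum
below a preset threshold.

Stronger signals mask weaker ones, so after each accepted fit the rank-1
model is subtracted (deflation) and the whole grid/FDR/selection cycle
re-runs on the residual, stopping when nothing significant remains or
when the iteration bound ``R* = min_k rank(D_k)`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RankOneFit, Signature, extract_signature, jammit_fit, residualize, svd_rank1
from .io_preprocess import DataMatrix, SuperMatrix, frobenius_scale, stack

__all__ = [
    "LambdaGrid",
    "FdrProfile",
    "IterationRecord",
    "JammitRun",
    "IterateConfig",
    "LoocvResult",
    "lambda_grid",
    "estimate_fdr",
    "select_lambda",
    "jammit_iterate",
    "loocv_signatures",
]


@dataclass
class LambdaGrid:
    """Strictly increasing penalty grid from 0 to ``lam_sup``.

    ``lam_sup = 2 * max_i |d_i . v0|`` (v0 the unit leading right
    singular vector) is the smallest penalty that zeroes the first
    soft-threshold update, hence yields an empty signature.
    """

    lambdas: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.ndim != 1 or len(self.lambdas) < 3:
            raise ValueError("grid needs at least 3 points")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.lambdas[0] != 0:
            raise ValueError("grid must start at 0")

    @property
    def L(self) -> int:
        return len(self.lambdas)

    @property
    def lam_sup(self) -> float:
        return float(self.lambdas[-1])


@dataclass
class FdrProfile:
    """Joint and per-type permutation-FDR sequences over a penalty grid."""

    grid: LambdaGrid
    s_obs: np.ndarray
    s_obs_per_block: dict[str, np.ndarray]
    fdr_joint: np.ndarray
    fdr_per_block: dict[str, np.ndarray]
    B: int
    seed: int

    def __post_init__(self) -> None:
        for arr in (self.fdr_joint, *self.fdr_per_block.values()):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("FDR values must lie in [0, 1]")


def lambda_grid(D: SuperMatrix | np.ndarray, L: int = 50, spacing: str = "linear") -> LambdaGrid:
    """Build an ``L``-point penalty grid from 0 to ``lam_sup`` for ``D``.

    ``spacing="geometric"`` concentrates points at small penalties
    (first point stays 0; the rest run geometrically from
    ``lam_sup / 10^3``), useful when the FDR profile drops early.
    """
    if L < 3:
        raise ValueError("need L >= 3")
    A = D.values if isinstance(D, SuperMatrix) else np.asarray(D, dtype=float)
    _, v0, sigma = svd_rank1(A)
    v0 = v0 / sigma  # unit right singular vector
    # 1e-9 relative headroom: the infimum 2*max|z| is attained only up to
    # rounding, and the sweep recomputes v0 through a different normalization
    lam_sup = 2.0 * float(np.max(np.abs(A @ v0))) * (1.0 + 1e-9)
    if spacing == "linear":
        lams = np.linspace(0.0, lam_sup, L)
    elif spacing == "geometric":
        lams = np.concatenate([[0.0], np.geomspace(lam_sup / 1e3, lam_sup, L - 1)])
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return LambdaGrid(lambdas=lams)


def _sweep_supports(
    A: np.ndarray,
    grid: LambdaGrid,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Boolean (L, p) detected-support matrix of jammit fits across the grid.

    The SVD initialization is computed once and shared across penalties.
    """
    init = svd_rank1(A)[:2]
    out = np.zeros((grid.L, A.shape[0]), dtype=bool)
    for li, lam in enumerate(grid.lambdas):
        fit = jammit_fit(A, lam, tol=tol, max_iter=max_iter, init=init)
        out[li] = fit.u != 0
    return out


def estimate_fdr(
    D: SuperMatrix,
    grid: LambdaGrid,
    B: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    estimator: str = "mean",
) -> FdrProfile:
    """Permutation-FDR profile of signature membership over a penalty grid.

    For each of ``B`` null replicates every row of the super-matrix is
    shuffled independently; FDR(lam) aggregates ``min(1, s_null/s_obs)``
    over replicates (``estimator`` "mean" or "median"), with the
    convention FDR = 1 wherever the observed signature is empty.
    Per-type profiles restrict both counts to one block's rows.
    """
    if B < 1:
        raise ValueError("need B >= 1")
    if estimator not in ("mean", "median"):
        raise ValueError("estimator must be 'mean' or 'median'")
    A = D.values
    rng = np.random.default_rng(seed)

    obs = _sweep_supports(A, grid, tol, max_iter)
    blocks = {tag: (a, b) for tag, a, b in D.block_map}
    s_obs = obs.sum(axis=1)
    s_obs_blk = {tag: obs[:, a:b].sum(axis=1) for tag, (a, b) in blocks.items()}

    ratios = np.empty((B, grid.L))
    ratios_blk = {tag: np.empty((B, grid.L)) for tag in blocks}
    for b_i in range(B):
        perm = rng.permuted(A, axis=1)  # independent within-row shuffles
        null = _sweep_supports(perm, grid, tol, max_iter)
        s_null = null.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(s_obs > 0, np.minimum(1.0, s_null / np.maximum(s_obs, 1)), 1.0)
        ratios[b_i] = r
        for tag, (a, b) in blocks.items():
            sn = null[:, a:b].sum(axis=1)
            so = s_obs_blk[tag]
            ratios_blk[tag][b_i] = np.where(
                so > 0, np.minimum(1.0, sn / np.maximum(so, 1)), 1.0
            )

    agg = np.mean if estimator == "mean" else np.median
    return FdrProfile(
        grid=grid,
        s_obs=s_obs,
        s_obs_per_block=s_obs_blk,
        fdr_joint=agg(ratios, axis=0),
        fdr_per_block={tag: agg(r, axis=0) for tag, r in ratios_blk.items()},
        B=B,
        seed=seed,
    )


def select_lambda(
    profile: FdrProfile, threshold: float = 0.05, mode: str = "min_fdr"
) -> float | None:
    """Pick ``lam*`` from the joint FDR profile; None when nothing qualifies.

    ``mode="min_fdr"`` (default): candidates are grid points that are
    local minima of the joint FDR (endpoints eligible; a plateau counts
    once, represented by its largest-penalty point) with FDR at or below
    ``threshold``; the smallest FDR wins and exact ties resolve toward
    the larger penalty, i.e. the sparser signature.

    ``mode="largest_signature"``: the smallest penalty whose FDR is at
    or below ``threshold`` (with a non-empty observed signature) — the
    largest signature meeting the significance bar.  This is the mode
    the multi-signal iteration uses: when a real shared signal is
    present the profile typically decays monotonically to ~0, and the
    sparsest point of that tail explains almost none of the signal,
    whereas the first crossing captures the full supported set before
    deflation.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    f = profile.fdr_joint
    if mode == "largest_signature":
        ok = np.nonzero((f <= threshold) & (profile.s_obs > 0))[0]
        return None if ok.size == 0 else float(profile.grid.lambdas[ok[0]])
    if mode != "min_fdr":
        raise ValueError("mode must be 'min_fdr' or 'largest_signature'")
    L = len(f)
    candidates: list[int] = []
    i = 0
    while i < L:
        j = i
        while j + 1 < L and f[j + 1] == f[i]:
            j += 1
        left_ok = i == 0 or f[i - 1] > f[i]
        right_ok = j == L - 1 or f[j + 1] > f[i]
        if left_ok and right_ok:
            candidates.append(j)  # plateau collapses to its largest-lambda point
        i = j + 1
    candidates = [c for c in candidates if f[c] <= threshold]
    if not candidates:
        return None
    best = min(candidates, key=lambda c: (f[c], -c))
    return float(profile.grid.lambdas[best])


@dataclass
class IterationRecord:
    """One accepted signal: the fit, its parsed signature, and the FDR evidence."""

    index: int
    fit: RankOneFit
    signature: Signature
    profile: FdrProfile
    lam_star: float
    residual_fraction: float  # ||residual after deflation||_F / ||initial D||_F


@dataclass
class JammitRun:
    """Full multi-signal run: ordered iteration records plus the stop reason."""

    records: list[IterationRecord]
    stop_reason: str
    r_star: int

    @property
    def n_signals(self) -> int:
        return len(self.records)


@dataclass
class IterateConfig:
    """Knobs for a multi-signal run (grid size, permutations, stopping)."""

    L: int = 50
    B: int = 100
    threshold: float = 0.05
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    max_iterations: int | None = None
    per_block_scale: bool = False
    estimator: str = "mean"
    spacing: str = "linear"
    selection: str = "largest_signature"  # see select_lambda


def _iteration_seeds(seed: int, count: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(count)]


def jammit_iterate(mmds: list[DataMatrix], config: IterateConfig | None = None) -> JammitRun:
    """Sequentially detect all significant rank-1 signals in an MMDS.

    Loop: scale the stacked matrix once, then repeatedly {grid -> FDR
    profile -> lam* -> fit -> record -> deflate} on the running
    residual.  Stops when no penalty passes the FDR threshold, when a
    fit comes back empty, or at ``R* = min_k rank(D_k)`` iterations.
    The FDR profile is re-estimated on each residual (its scale and
    dominant structure change after every deflation).
    """
    cfg = config or IterateConfig()
    sm = frobenius_scale(stack(mmds), per_block=cfg.per_block_scale)
    r_star = int(min(np.linalg.matrix_rank(m.values) for m in mmds))
    limit = r_star if cfg.max_iterations is None else min(r_star, cfg.max_iterations)
    seeds = _iteration_seeds(cfg.seed, max(limit, 1))

    residual = sm
    records: list[IterationRecord] = []
    stop_reason = "iteration bound reached"
    for it in range(1, limit + 1):
        grid = lambda_grid(residual, cfg.L, spacing=cfg.spacing)
        profile = estimate_fdr(
            residual, grid, B=cfg.B, seed=seeds[it - 1],
            tol=cfg.tol, max_iter=cfg.max_iter, estimator=cfg.estimator,
        )
        lam_star = select_lambda(profile, cfg.threshold, mode=cfg.selection)
        if lam_star is None:
            stop_reason = "no significant lambda"
            break
        fit = jammit_fit(residual, lam_star, tol=cfg.tol, max_iter=cfg.max_iter)
        if fit.empty:
            stop_reason = "empty fit"
            break
        sig = extract_signature(fit, residual)
        residual = residualize(residual, fit)
        frac = float(np.linalg.norm(residual.values) / np.linalg.norm(sm.values))
        records.append(
            IterationRecord(
                index=it, fit=fit, signature=sig, profile=profile,
                lam_star=lam_star, residual_fraction=frac,
            )
        )
    return JammitRun(records=records, stop_reason=stop_reason, r_star=r_star)


@dataclass
class LoocvResult:
    """Minus-one signature stability summary at a fixed penalty."""

    full_signature: Signature
    minus_one_signatures: list[Signature]
    recapitulation: np.ndarray  # fraction of the full signature recovered, per fold
    intersection: set[tuple[str, str]]  # (variable_id, dtype_tag) common to all folds

    @property
    def mean_recapitulation(self) -> float:
        return float(self.recapitulation.mean())


def loocv_signatures(
    mmds: list[DataMatrix],
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    per_block_scale: bool = False,
) -> LoocvResult:
    """Leave-one-sample-out robustness of the signature at a fixed penalty.

    For each sample j the j-th column is removed from every block, the
    model is refit at the same ``lam``, and the resulting minus-one
    signature is compared to the full-data signature; the intersection
    across all folds is the perturbation-robust signature.
    """
    n = mmds[0].n
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    sm_full = frobenius_scale(stack(mmds), per_block=per_block_scale)
    fit_full = jammit_fit(sm_full, lam, tol=tol, max_iter=max_iter)
    sig_full = extract_signature(fit_full, sm_full)
    if sig_full.s == 0:
        raise ValueError("full-data signature is empty; use a smaller lam")
    full_keys = {(vid, tag) for vid, tag, _ in sig_full.entries}

    sigs: list[Signature] = []
    recap = np.empty(n)
    inter: set[tuple[str, str]] | None = None
    for j in range(n):
        keep = [c for c in range(n) if c != j]
        reduced = [
            DataMatrix(
                values=m.values[:, keep],
                variable_ids=m.variable_ids,
                sample_ids=[m.sample_ids[c] for c in keep],
                dtype_tag=m.dtype_tag,
            )
            for m in mmds
        ]
        sm_j = frobenius_scale(stack(reduced), per_block=per_block_scale)
        fit_j = jammit_fit(sm_j, lam, tol=tol, max_iter=max_iter)
        sig_j = extract_signature(fit_j, sm_j)
        keys_j = {(vid, tag) for vid, tag, _ in sig_j.entries}
        sigs.append(sig_j)
        recap[j] = len(keys_j & full_keys) / len(full_keys)
        inter = keys_j if inter is None else (inter & keys_j)

    return LoocvResult(
        full_signature=sig_full,
        minus_one_signatures=sigs,
        recapitulation=recap,
        intersection=inter or set(),
    )
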