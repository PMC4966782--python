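"""Support-recovery evaluation: penalty-swept ROC curves and detector comparison.

Sweeping the l1 penalty from 0 to ``lam_sup`` shrinks the detected row
set from everything to nothing; scoring each detected set against the
planted support traces a ROC curve whose area (AUROC) summarizes how
well the method separates signal-carrying rows from noise rows.  A
pluggable detector interface lets alternative methods be scored on the
same simulations; per-simulation AUROC differences (dAUROC, positive
favoring the first detector) are compared with an exact binomial sign
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.metrics import roc_auc_score

from .core import jammit_fit, residualize, svd_rank1
from .io_preprocess import SuperMatrix
from .selection import LambdaGrid, lambda_grid
from .simulation import SIGNAL_NAMES, SimulatedMMDS, SimulationConfig, simulate_mmds

__all__ = [
    "RocResult",
    "DetectorResult",
    "Detector",
    "JammitSweepDetector",
    "SvdThresholdDetector",
    "RandomScoreDetector",
    "roc_from_sweep",
    "delta_auroc",
    "sign_test",
    "compare_over_sims",
]


@dataclass
class RocResult:
    """ROC of a penalty sweep against a known support."""

    grid: LambdaGrid
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


def _auroc_from_points(fpr: np.ndarray, tpr: np.ndarray) -> float:
    pts = np.unique(
        np.column_stack([np.append(fpr, (0.0, 1.0)), np.append(tpr, (0.0, 1.0))]),
        axis=0,
    )  # sorts by (fpr, tpr) and drops duplicate points
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_from_sweep(
    D: SuperMatrix,
    grid: LambdaGrid,
    truth: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> RocResult:
    """ROC/AUROC of the sparse-fit support across a penalty grid.

    For each penalty the detected set is the non-zero rows of the fitted
    eigen-array; TPR/FPR are computed against ``truth`` and the area is
    the trapezoid over FPR-sorted points augmented with (0,0) and (1,1).
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.shape[0] != D.p:
        raise ValueError("truth length must equal the number of stacked rows")
    npos = int(truth.sum())
    if npos == 0 or npos == truth.shape[0]:
        raise ValueError("truth must contain at least one positive and one negative")
    init = svd_rank1(D.values)[:2]
    tpr = np.empty(grid.L)
    fpr = np.empty(grid.L)
    for li, lam in enumerate(grid.lambdas):
        detected = jammit_fit(D.values, lam, tol=tol, max_iter=max_iter, init=init).u != 0
        tpr[li] = (detected & truth).sum() / npos
        fpr[li] = (detected & ~truth).sum() / (truth.shape[0] - npos)
    return RocResult(grid=grid, tpr=tpr, fpr=fpr, auroc=_auroc_from_points(fpr, tpr))


@dataclass
class DetectorResult:
    """Per-simulation AUROC values of one detector, per planted signal."""

    name: str
    aurocs: dict[str, np.ndarray]  # signal name -> (n_sims,) array

    def __post_init__(self) -> None:
        for sig, arr in self.aurocs.items():
            arr = np.asarray(arr, dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"AUROC out of [0, 1] for signal {sig!r}")
            self.aurocs[sig] = arr


def delta_auroc(a: DetectorResult, b: DetectorResult) -> dict[str, np.ndarray]:
    """Per-simulation AUROC differences a - b (positive favors ``a``)."""
    if set(a.aurocs) != set(b.aurocs):
        raise ValueError("detector results cover different signals")
    out = {}
    for sig in a.aurocs:
        if a.aurocs[sig].shape != b.aurocs[sig].shape:
            raise ValueError(f"signal {sig!r}: different number of simulations")
        out[sig] = a.aurocs[sig] - b.aurocs[sig]
    return out


def sign_test(deltas: np.ndarray) -> float:
    """Exact two-sided binomial sign test on the non-zero signs of ``deltas``."""
    deltas = np.asarray(deltas, dtype=float)
    nz = deltas[deltas != 0]
    if nz.size == 0:
        return 1.0
    k = int((nz > 0).sum())
    return float(binomtest(k, nz.size, 0.5).pvalue)


def _match_iterations(vs: list[np.ndarray], signals: dict[str, np.ndarray]) -> dict[str, int]:
    """Assign fitted eigen-signals to planted signals by largest |correlation|."""
    names = list(signals)
    corr = np.zeros((len(vs), len(names)))
    for i, v in enumerate(vs):
        for j, name in enumerate(names):
            sd = v.std()
            corr[i, j] = 0.0 if sd == 0 else abs(np.corrcoef(v, signals[name])[0, 1])
    assignment: dict[str, int] = {}
    used_iters: set[int] = set()
    # greedy: strongest |corr| first
    for i, j in sorted(
        ((i, j) for i in range(len(vs)) for j in range(len(names))),
        key=lambda ij: -corr[ij],
    ):
        if i in used_iters or names[j] in assignment:
            continue
        assignment[names[j]] = i
        used_iters.add(i)
    return assignment


class Detector:
    """Plug-in contract: per-signal AUROCs on one simulated MMDS.

    Implementations receive the scaled super-matrix plus the ground
    truth (supports and planted signals, used only for matching fitted
    components to signals and for scoring) and return an AUROC per
    planted signal.  External methods can either implement ``evaluate``
    directly or subclass :class:`ScoreDetector` to supply per-row scores.
    """

    name: str = "detector"

    def evaluate(self, sm: SuperMatrix, sim: SimulatedMMDS, L: int) -> dict[str, float]:
        raise NotImplementedError


class ScoreDetector(Detector):
    """Detector that ranks rows by a real score, one score vector per signal."""

    def scores(self, sm: SuperMatrix, sim: SimulatedMMDS) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def evaluate(self, sm: SuperMatrix, sim: SimulatedMMDS, L: int) -> dict[str, float]:
        out = {}
        for name, sc in self.scores(sm, sim).items():
            sc = np.asarray(sc, dtype=float)
            if sc.shape[0] != sm.p:
                raise ValueError(
                    f"detector {self.name!r} returned {sc.shape[0]} scores "
                    f"for {sm.p} rows"
                )
            out[name] = float(roc_auc_score(sim.stacked_truth(name), sc))
        return out


class JammitSweepDetector(Detector):
    """The sparse rank-1 penalty sweep, one deflation iteration per signal.

    Iteration 1 sweeps the super-matrix; the fitted (lam = 0) rank-1
    component is then deflated and iteration 2 sweeps the residual.
    Iterations are matched to planted signals by the larger
    |correlation| of their eigen-signals with each signal.
    """

    name = "jammit"

    def __init__(self, tol: float = 1e-6, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def evaluate(self, sm: SuperMatrix, sim: SimulatedMMDS, L: int) -> dict[str, float]:
        mats: list[SuperMatrix] = []
        vs: list[np.ndarray] = []
        current = sm
        for _ in sim.signals:
            fit0 = jammit_fit(current.values, 0.0, tol=self.tol, max_iter=self.max_iter)
            mats.append(current)
            vs.append(fit0.v)
            current = residualize(current, fit0)
        match = _match_iterations(vs, sim.signals)
        out = {}
        for name, it in match.items():
            grid = lambda_grid(mats[it], L)
            roc = roc_from_sweep(
                mats[it], grid, sim.stacked_truth(name),
                tol=self.tol, max_iter=self.max_iter,
            )
            out[name] = roc.auroc
        return out


class SvdThresholdDetector(ScoreDetector):
    """Baseline: rank rows by |loading| in the plain SVD's leading eigen-arrays.

    The r-th left singular vector scores the signal whose planted
    eigen-signal best correlates with the r-th right singular vector.
    """

    name = "svd-threshold"

    def scores(self, sm: SuperMatrix, sim: SimulatedMMDS) -> dict[str, np.ndarray]:
        U, _, Vt = np.linalg.svd(sm.values, full_matrices=False)
        k = len(sim.signals)
        match = _match_iterations([Vt[r] for r in range(k)], sim.signals)
        return {name: np.abs(U[:, r]) for name, r in match.items()}


class RandomScoreDetector(ScoreDetector):
    """Null baseline: i.i.d. uniform row scores (AUROC ~ 0.5)."""

    name = "random"

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def scores(self, sm: SuperMatrix, sim: SimulatedMMDS) -> dict[str, np.ndarray]:
        return {name: self.rng.uniform(size=sm.p) for name in sim.signals}


@dataclass
class ComparisonResult:
    """Per-simulation AUROC table plus dAUROC summaries vs the reference."""

    table: pd.DataFrame  # columns: sim, signal, detector, auroc
    reference: str
    deltas: dict[tuple[str, str], np.ndarray]  # (detector, signal) -> dAUROC
    sign_p: dict[tuple[str, str], float]


def compare_over_sims(
    config: SimulationConfig,
    detectors: list[Detector],
    n_sims: int = 20,
    seed: int = 0,
    L: int = 25,
    reference: Detector | None = None,
) -> ComparisonResult:
    """Score the penalty sweep against alternative detectors over simulations.

    Each simulation is drawn from ``config`` with an independent seed;
    every detector scores both planted signals; dAUROC (reference minus
    detector, positive favoring the reference sweep) is summarized per
    detector and signal with an exact binomial sign test.
    """
    if n_sims < 5:
        raise ValueError("need n_sims >= 5")
    if not detectors:
        raise ValueError("need at least one detector besides the reference")
    ref = reference or JammitSweepDetector()
    all_dets = [ref] + [d for d in detectors if d is not ref]
    # de-duplicate display names so a detector can be compared against itself
    names: list[str] = []
    for det in all_dets:
        name = det.name
        while name in names:
            name += "#2"
        names.append(name)
    seeds = np.random.SeedSequence(seed).spawn(n_sims)

    rows = []
    for si, child in enumerate(seeds):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        sim = simulate_mmds(
            SimulationConfig(**{**config.__dict__, "seed": sim_seed})
        )
        sm = sim.supermatrix()
        for det, name in zip(all_dets, names):
            for sig_name, auc in det.evaluate(sm, sim, L).items():
                rows.append(
                    {"sim": si, "signal": sig_name, "detector": name, "auroc": auc}
                )
    table = pd.DataFrame(rows)

    deltas: dict[tuple[str, str], np.ndarray] = {}
    sign_p: dict[tuple[str, str], float] = {}
    ref_name = names[0]
    for name in names[1:]:
        for sig_name in SIGNAL_NAMES:
            a = table.query("detector == @ref_name and signal == @sig_name").sort_values("sim")
            b = table.query("detector == @name and signal == @sig_name").sort_values("sim")
            d = a["auroc"].to_numpy() - b["auroc"].to_numpy()
            deltas[(name, sig_name)] = d
            sign_p[(name, sig_name)] = sign_test(d)
    return ComparisonResult(table=table, reference=ref_name, deltas=deltas, sign_p=sign_p)
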