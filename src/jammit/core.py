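"""Sparse rank-1 approximation of a stacked multi-omics matrix.

Given the super-matrix D (p variables x n samples), we seek the rank-1
approximation ``D ~ u v^T`` minimizing

    E(u, v, lam) = ||D - u v^T||_F^2 + lam * ||u||_1,   subject to v = D^T u,

where ``u`` (the eigen-array) carries per-variable loadings that the l1
penalty drives to exact zeros, and ``v`` (the eigen-signal) is a dense
per-sample signal shared by every stacked data type.  The non-zero
entries of ``u`` define a multi-modal signature.  The solver alternates
the closed-form soft-threshold update of ``u`` with the least-squares
update of ``v``, starting from the leading singular pair; at lam = 0 it
reduces to the classical best rank-1 SVD approximation.

For numerical stability ``v`` is kept at unit l2 norm inside the loop
(each unit-sphere v-update is then the exact minimizer of E for fixed u,
so the objective trace is non-increasing); on exit ``u`` is normalized
to unit l2 norm and ``v`` recomputed as ``D^T u`` so the returned pair
honors the constraint with a scale-consistent outer product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import SuperMatrix

__all__ = [
    "RankOneFit",
    "Signature",
    "svd_rank1",
    "sparse_u_update",
    "jammit_fit",
    "extract_signature",
    "residualize",
]


@dataclass
class RankOneFit:
    """Result of one sparse rank-1 fit.

    ``u`` has unit l2 norm unless the fit is empty (all-zero); ``v``
    satisfies ``v = D^T u`` for the matrix the fit was computed on.
    """

    u: np.ndarray
    v: np.ndarray
    lam: float
    n_iter: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    @property
    def s(self) -> int:
        """Signature size: number of non-zero eigen-array entries."""
        return int(np.count_nonzero(self.u))

    @property
    def empty(self) -> bool:
        return self.s == 0


@dataclass
class Signature:
    """Non-zero eigen-array entries parsed per data type by stacking order."""

    entries: list[tuple[str, str, float]]  # (variable_id, dtype_tag, weight)
    per_block_counts: dict[str, int]

    @property
    def s(self) -> int:
        return len(self.entries)

    def variable_ids(self) -> set[str]:
        return {vid for vid, _, _ in self.entries}

    def block_entries(self, tag: str) -> list[tuple[str, float]]:
        return [(vid, w) for vid, t, w in self.entries if t == tag]


def _as_array(D) -> np.ndarray:
    if isinstance(D, SuperMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def svd_rank1(D) -> tuple[np.ndarray, np.ndarray, float]:
    """Leading singular triple ``(u0, v0, sigma)`` of D.

    ``u0`` is the unit left singular vector with its largest-magnitude
    entry made positive (the SVD sign is arbitrary) and ``v0 = sigma *
    (unit right singular vector)``, so ``u0 v0^T`` is the Eckart–Young
    best rank-1 approximation of D.
    """
    A = _as_array(D)
    if not np.any(A):
        raise ValueError("zero matrix has no rank-1 approximation")
    # thin SVD of the smaller Gram side is wasteful to hand-roll; numpy's
    # LAPACK svd on a p x n matrix with n << p is fine at our sizes
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    u0, sigma, v0 = U[:, 0], float(S[0]), Vt[0]
    sign = np.sign(u0[np.argmax(np.abs(u0))])
    u0 = sign * u0
    v0 = sign * sigma * v0
    return u0, v0, sigma


def sparse_u_update(D, v: np.ndarray, lam: float) -> np.ndarray:
    """Exact minimizer of ``||D - u v^T||_F^2 + lam ||u||_1`` for fixed v.

    Separable per row: with ``z_i = d_i . v``,
    ``u_i = sign(z_i) * max(|z_i| - lam/2, 0) / ||v||^2`` — the familiar
    soft-threshold (asymmetric-LASSO) shrinkage with threshold lam/2.
    """
    A = _as_array(D)
    v = np.asarray(v, dtype=float)
    vv = float(v @ v)
    if vv == 0:
        raise ValueError("v must be non-zero")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    z = A @ v
    return np.sign(z) * np.maximum(np.abs(z) - lam / 2.0, 0.0) / vv


def _objective(A: np.ndarray, u: np.ndarray, v: np.ndarray, lam: float) -> float:
    # ||A - u v^T||_F^2 expanded to avoid forming the p x n outer product
    return float(
        np.linalg.norm(A) ** 2
        - 2.0 * (u @ (A @ v))
        + (u @ u) * (v @ v)
        + lam * np.abs(u).sum()
    )


def jammit_fit(
    D,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    debias: bool = True,
) -> RankOneFit:
    """Alternating sparse rank-1 fit of the (super-)matrix D at penalty ``lam``.

    Starting from the leading singular pair (or ``init = (u0, v0)``,
    e.g. cached across a lambda sweep), alternate the soft-threshold
    u-update against the unit-normalized eigen-signal with the v-update
    ``v <- D^T u`` until the relative l2 change of both factors drops
    below ``tol``.  If ``u`` shrinks to all-zero the fit is returned
    immediately as empty (s = 0).

    With ``debias=True`` (default) the selected support is refit by
    unpenalized least squares against the final eigen-signal before the
    factors are returned: the l1 stage picks which rows enter the
    signature, the refit removes the soft-threshold's downward bias on
    their weights.  The support, and the fit at lam = 0, are unaffected;
    deflating the debiased outer product leaves no coherent shrinkage
    remnant behind, which keeps sequential extraction clean.
    """
    A = _as_array(D)
    if tol <= 0 or max_iter < 1:
        raise ValueError("need tol > 0 and max_iter >= 1")
    if init is None:
        u, v, _ = svd_rank1(A)
    else:
        u, v = (np.asarray(x, dtype=float) for x in init)
    v_unit = v / np.linalg.norm(v)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_new = sparse_u_update(A, v_unit, lam)  # ||v_unit|| = 1
        if not np.all(np.isfinite(u_new)):
            raise FloatingPointError(f"non-finite u at iteration {it}")
        trace.append(_objective(A, u_new, v_unit, lam))
        if not np.any(u_new):
            return RankOneFit(
                u=np.zeros(A.shape[0]),
                v=np.zeros(A.shape[1]),
                lam=lam,
                n_iter=it,
                converged=True,
                objective_trace=trace,
            )
        v_new = A.T @ u_new
        v_new_unit = v_new / np.linalg.norm(v_new)
        du = np.linalg.norm(u_new - u) / max(np.linalg.norm(u), np.finfo(float).tiny)
        dv = np.linalg.norm(v_new_unit - v_unit) / 1.0
        u, v_unit = u_new, v_new_unit
        if du < tol and dv < tol:
            converged = True
            break

    if debias and lam > 0:
        z = A @ v_unit
        u = np.where(u != 0, z, 0.0)
    u_hat = u / np.linalg.norm(u)
    sign = np.sign(u_hat[np.argmax(np.abs(u_hat))])
    u_hat = sign * u_hat
    v_out = A.T @ u_hat
    if not np.all(np.isfinite(v_out)):
        raise FloatingPointError(f"non-finite v at iteration {it}")
    return RankOneFit(
        u=u_hat,
        v=v_out,
        lam=lam,
        n_iter=it,
        converged=converged,
        objective_trace=trace,
    )


def extract_signature(fit: RankOneFit, sm: SuperMatrix) -> Signature:
    """Parse the non-zero eigen-array entries per data type, in stacking order."""
    if fit.u.shape[0] != sm.p:
        raise ValueError(
            f"eigen-array length {fit.u.shape[0]} does not match super-matrix p={sm.p}"
        )
    entries: list[tuple[str, str, float]] = []
    counts = {tag: 0 for tag, _, _ in sm.block_map}
    for i in np.nonzero(fit.u)[0]:
        tag = sm.block_of_row(int(i))
        entries.append((sm.variable_ids[i], tag, float(fit.u[i])))
        counts[tag] += 1
    return Signature(entries=entries, per_block_counts=counts)


def residualize(D, fit: RankOneFit):
    """Deflate: ``D' = D - u v^T``, exposing weaker signals masked by the fit.

    Accepts and returns the same container kind it was given (array in,
    array out; SuperMatrix in, SuperMatrix out with scaling flag cleared).
    """
    A = _as_array(D)
    if fit.u.shape[0] != A.shape[0] or fit.v.shape[0] != A.shape[1]:
        raise ValueError("fit factors do not match matrix shape")
    resid = A - np.outer(fit.u, fit.v)
    if isinstance(D, SuperMatrix):
        return SuperMatrix(
            values=resid,
            block_map=list(D.block_map),
            variable_ids=list(D.variable_ids),
            sample_ids=list(D.sample_ids),
            frobenius_applied=False,
        )
    return resid
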