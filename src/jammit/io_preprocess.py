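"""Reading, preprocessing and stacking of multi-modal data matrices.

A multi-modal data set (MMDS) is a collection of variables-by-samples
matrices — one per data type (mRNA, microRNA, methylation, imaging
covariates, ...) — measured on one common, ordered set of samples.  This
module loads each matrix from TSV, applies the type-appropriate
preprocessing (log2 or generalized log2, quantile normalization,
Beta-to-M transform, row centering), vertically stacks the per-type
matrices into a single super-matrix and scales it to unit Frobenius
norm.  The sparse rank-1 machinery in :mod:`jammit.core` operates on the
resulting :class:`SuperMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DataMatrix",
    "SuperMatrix",
    "SurvivalRecords",
    "read_data_matrix",
    "write_data_matrix",
    "read_survival",
    "write_survival",
    "log2_transform",
    "quantile_normalize",
    "beta_to_m",
    "row_center",
    "impute_row_median",
    "stack",
    "frobenius_scale",
]


def _check_unique(ids, what: str) -> None:
    seen: dict = {}
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen[i] = True


@dataclass
class DataMatrix:
    """One data type's variables-by-samples matrix.

    Parameters
    ----------
    values
        Real ``(p_k, n)`` array; must be finite.
    variable_ids
        ``p_k`` unique row identifiers.
    sample_ids
        ``n`` unique, ordered column identifiers shared across the MMDS.
    dtype_tag
        Free-form data-type label, e.g. ``"mRNA"`` or ``"meth_beta"``.
    """

    values: np.ndarray
    variable_ids: list[str]
    sample_ids: list[str]
    dtype_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.variable_ids = list(self.variable_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (variables x samples)")
        p, n = self.values.shape
        if p < 1 or n < 2:
            raise ValueError(f"need p_k >= 1 and n >= 2, got shape {(p, n)}")
        if len(self.variable_ids) != p:
            raise ValueError("variable_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")
        _check_unique(self.variable_ids, "variable")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at variable {self.variable_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        """Copy of this matrix with new ``values`` (same IDs and tag)."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SuperMatrix:
    """Vertical stack of the per-type matrices of an MMDS.

    ``block_map`` records, in stacking order, each block's
    ``(dtype_tag, row_start, row_end)`` half-open row range so that a
    fitted eigen-array can be parsed back into type-specific signatures.
    """

    values: np.ndarray
    block_map: list[tuple[str, int, int]]
    variable_ids: list[str]
    sample_ids: list[str]
    frobenius_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, n = self.values.shape
        if self.block_map[0][1] != 0 or self.block_map[-1][2] != p:
            raise ValueError("block_map does not partition the row range")
        for (_, a0, a1), (_, b0, _) in zip(self.block_map, self.block_map[1:]):
            if a1 != b0:
                raise ValueError("block_map ranges are not contiguous")
        if len(self.variable_ids) != p or len(self.sample_ids) != n:
            raise ValueError("ID lists do not match matrix shape")
        if self.frobenius_applied:
            nrm = np.linalg.norm(self.values)
            if abs(nrm - 1.0) > 1e-12:
                raise ValueError("frobenius_applied set but norm != 1")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def block(self, tag: str) -> np.ndarray:
        """Return the sub-matrix of the block tagged ``tag``."""
        for t, a, b in self.block_map:
            if t == tag:
                return self.values[a:b]
        raise KeyError(tag)

    def block_of_row(self, i: int) -> str:
        for t, a, b in self.block_map:
            if a <= i < b:
                return t
        raise IndexError(i)


@dataclass
class SurvivalRecords:
    """Per-sample follow-up: time on study and censoring indicator.

    ``censored`` follows the 0 = event observed, 1 = censored coding.
    """

    sample_ids: list[str]
    time: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.censored = np.asarray(self.censored, dtype=int)
        m = len(self.sample_ids)
        if self.time.shape != (m,) or self.censored.shape != (m,):
            raise ValueError("time/censored not aligned with sample_ids")
        _check_unique(self.sample_ids, "sample")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.censored, (0, 1)).all():
            raise ValueError("censored must be coded 0/1")

    @property
    def events(self) -> np.ndarray:
        """Event indicator (1 = death/event observed)."""
        return 1 - self.censored


# ---------------------------------------------------------------------------
# File I/O


def read_data_matrix(path, dtype_tag: str) -> DataMatrix:
    """Load a variables-by-samples TSV (header = sample IDs, col 1 = variable IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & ~df.isna()
    if bad.any().any() or df.isna().any().any():
        mask = body.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at variable "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return DataMatrix(
        values=body.to_numpy(dtype=float),
        variable_ids=[str(v) for v in df.index],
        sample_ids=[str(c) for c in df.columns],
        dtype_tag=dtype_tag,
    )


def write_data_matrix(m: DataMatrix, path) -> None:
    """Write a :class:`DataMatrix` as TSV (full float precision round-trips)."""
    df = pd.DataFrame(m.values, index=m.variable_ids, columns=m.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_survival(path) -> SurvivalRecords:
    """Load a survival TSV with columns sample_id, time, censored."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time", "censored"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return SurvivalRecords(
        sample_ids=list(df["sample_id"]),
        time=df["time"].to_numpy(float),
        censored=df["censored"].to_numpy(int),
    )


def write_survival(rec: SurvivalRecords, path) -> None:
    pd.DataFrame(
        {"sample_id": rec.sample_ids, "time": rec.time, "censored": rec.censored}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing transforms


def log2_transform(m: DataMatrix, glog_c: float = 0.0) -> DataMatrix:
    """log2 (``glog_c = 0``) or generalized log2 transform.

    The generalized transform ``glog2(x) = log2((x + sqrt(x^2 + c)) / 2)``
    is defined for all real x and approaches plain log2 as c -> 0+; it is
    the standard variance-stabilizing choice for background-subtracted
    arrays that can contain zeros or small negatives.
    """
    if glog_c < 0:
        raise ValueError("glog_c must be non-negative")
    x = m.values
    if glog_c == 0:
        if np.any(x <= 0):
            raise ValueError("log2 with glog_c=0 requires strictly positive values")
        out = np.log2(x)
    else:
        out = np.log2((x + np.sqrt(x * x + glog_c)) / 2.0)
    return m.with_values(out)


def quantile_normalize(m: DataMatrix) -> DataMatrix:
    """Force every column onto the common per-rank cross-column mean distribution.

    Ties within a column receive the mean of their ranks' reference
    values (average-rank convention).
    """
    x = m.values
    ref = np.sort(x, axis=0).mean(axis=1)  # reference distribution per rank
    p = x.shape[0]
    out = np.empty_like(x)
    grid = np.arange(1, p + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return m.with_values(out)


def beta_to_m(m: DataMatrix, eps: float = 1e-6) -> DataMatrix:
    """Logit-transform methylation Beta-values to M-values, M = log2(b/(1-b)).

    Values are clipped to ``[eps, 1-eps]`` first so boundary Betas map to
    finite M-values; anything outside [0, 1] is rejected.
    """
    x = m.values
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("Beta-values must lie in [0, 1]")
    b = np.clip(x, eps, 1 - eps)
    return m.with_values(np.log2(b / (1 - b)))


def row_center(m: DataMatrix) -> DataMatrix:
    """Subtract each row's mean (idempotent)."""
    if m.n < 2:
        raise ValueError("row centering needs n >= 2")
    return m.with_values(m.values - m.values.mean(axis=1, keepdims=True))


def impute_row_median(values: np.ndarray) -> np.ndarray:
    """Row-median imputation on a raw array (``DataMatrix`` rejects NaNs itself).

    Missing values are rejected by default throughout the package; this
    helper is the opt-in alternative, applied to the raw array before a
    :class:`DataMatrix` is constructed. Rows with no finite value fail.
    """
    x = np.array(values, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        med = np.nanmedian(np.where(np.isfinite(x), x, np.nan), axis=1)
    if np.any(~np.isfinite(med[bad.any(axis=1)])):
        raise ValueError("row with no finite values cannot be imputed")
    rows = np.nonzero(bad)[0]
    x[bad] = med[rows]
    return x


# ---------------------------------------------------------------------------
# Stacking and scaling


def stack(mmds: list[DataMatrix], reorder: bool = False) -> SuperMatrix:
    """Vertically stack the matrices of an MMDS into a super-matrix.

    All matrices must share the sample IDs of the first matrix, in the
    same order; with ``reorder=True`` later blocks are permuted by ID to
    the first block's column order.
    """
    if not mmds:
        raise ValueError("empty MMDS")
    ref_ids = mmds[0].sample_ids
    blocks = []
    block_map = []
    variable_ids: list[str] = []
    start = 0
    for m in mmds:
        if m.sample_ids != ref_ids:
            if reorder and set(m.sample_ids) == set(ref_ids):
                idx = [m.sample_ids.index(s) for s in ref_ids]
                vals = m.values[:, idx]
            else:
                missing = sorted(set(ref_ids) ^ set(m.sample_ids))
                detail = (
                    f"mismatched IDs: {missing}" if missing else "sample order differs"
                )
                raise ValueError(
                    f"block {m.dtype_tag!r} sample IDs do not align ({detail}); "
                    "pass reorder=True to permute by ID"
                )
        else:
            vals = m.values
        blocks.append(vals)
        block_map.append((m.dtype_tag, start, start + m.p))
        variable_ids.extend(m.variable_ids)
        start += m.p
    return SuperMatrix(
        values=np.vstack(blocks),
        block_map=block_map,
        variable_ids=variable_ids,
        sample_ids=list(ref_ids),
        frobenius_applied=False,
    )


def frobenius_scale(sm: SuperMatrix, per_block: bool = False) -> SuperMatrix:
    """Scale the super-matrix to unit Frobenius norm.

    With ``per_block=True`` each block is first scaled to unit Frobenius
    norm individually before the global scaling, equalizing the energy
    contributed by data types of very different size or dynamic range.
    """
    vals = sm.values.copy()
    if per_block:
        for tag, a, b in sm.block_map:
            nrm = np.linalg.norm(vals[a:b])
            if nrm == 0:
                raise ValueError(f"zero block {tag!r} cannot be scaled")
            vals[a:b] /= nrm
    nrm = np.linalg.norm(vals)
    if nrm == 0:
        raise ValueError("zero matrix cannot be Frobenius-scaled")
    vals /= nrm
    # renormalize once more to absorb rounding in the division
    vals /= np.linalg.norm(vals)
    return SuperMatrix(
        values=vals,
        block_map=list(sm.block_map),
        variable_ids=list(sm.variable_ids),
        sample_ids=list(sm.sample_ids),
        frobenius_applied=True,
    )
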