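"""Synthetic multi-modal data with planted sparse signals.

Each simulated MMDS has K (default 2) blocks whose row counts are drawn
from {1000, 2000, ..., 10000}, sharing n = 50 samples.  Two per-sample
signals are planted on small, disjoint row subsets of every block: a
step signal separating the first n/2 samples from the last n/2 (a
differential-expression surrogate) and a random signal standing in for
an unmeasured sample attribute.  Supported rows carry the signal times a
row-specific amplitude; everything is buried in i.i.d. Gaussian noise,
with the signal matrix rescaled so the realized signal-to-noise ratio
(variance ratio of the vectorized signal and noise matrices, in dB) hits
the requested target.  Ground truth — supports, signals, realized SNR —
is emitted alongside the data and never recomputed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import DataMatrix, SuperMatrix, frobenius_scale, stack

__all__ = [
    "SimulationConfig",
    "SimulatedMMDS",
    "make_step_signal",
    "make_random_signal",
    "snr_db",
    "simulate_mmds",
]

SIGNAL_NAMES = ("step", "rand")


def make_step_signal(n: int) -> np.ndarray:
    """Step signal: +1 on the first n/2 samples, -1 on the rest (mean 0, var 1)."""
    if n % 2 != 0:
        raise ValueError("step signal needs an even number of samples")
    return np.concatenate([np.ones(n // 2), -np.ones(n // 2)])


def make_random_signal(n: int, seed) -> np.ndarray:
    """Standard-normal draws, centered and scaled to unit sample variance.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = x - x.mean()
    return x / x.std()


def snr_db(sigma: np.ndarray, noise: np.ndarray) -> float:
    """Signal-to-noise ratio in dB: 10*log10(var(signal)/var(noise)), vectorized."""
    vn = float(np.var(np.asarray(noise, dtype=float)))
    if vn == 0:
        raise ValueError("noise has zero variance")
    vs = float(np.var(np.asarray(sigma, dtype=float)))
    return 10.0 * np.log10(vs / vn)


@dataclass
class SimulationConfig:
    """Study design of one simulated MMDS.

    Defaults mirror the two-block, 50-sample design with block sizes
    drawn from {1000, ..., 10000}; support_fraction (with a floor of
    ``min_support`` rows) fixes how many rows carry each signal in each
    block, and amplitudes are uniform on [0.5, 1.5] with random sign.
    """

    K: int = 2
    p_choices: tuple[int, ...] = tuple(range(1000, 10001, 1000))
    n: int = 50
    support_fraction: float = 0.02
    min_support: int = 20
    snr_db: float = 0.0
    amplitude_low: float = 0.5
    amplitude_high: float = 1.5
    noise: str = "gaussian"  # or "t5" for heavier tails
    orthogonalize_signals: bool = False
    seed: int = 0
    dtype_tags: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.support_fraction < 1):
            raise ValueError("support_fraction must be in (0, 1)")
        if self.n % 2 != 0:
            raise ValueError("n must be even (step signal)")
        if self.noise not in ("gaussian", "t5"):
            raise ValueError("noise must be 'gaussian' or 't5'")

    def tags(self) -> tuple[str, ...]:
        if self.dtype_tags is not None:
            if len(self.dtype_tags) != self.K:
                raise ValueError("dtype_tags length must equal K")
            return self.dtype_tags
        return tuple(f"type{k + 1}" for k in range(self.K))


@dataclass
class SimulatedMMDS:
    """A simulated MMDS with full ground truth."""

    blocks: list[DataMatrix]
    signal_blocks: list[np.ndarray]
    noise_blocks: list[np.ndarray]
    support: dict[str, dict[str, np.ndarray]]  # tag -> signal name -> row indices
    signals: dict[str, np.ndarray]  # signal name -> per-sample vector
    realized_snr_db: float
    config: SimulationConfig = field(repr=False)

    def supermatrix(self, per_block_scale: bool = False) -> SuperMatrix:
        """Stack the blocks and scale to unit Frobenius norm."""
        return frobenius_scale(stack(self.blocks), per_block=per_block_scale)

    def stacked_truth(self, signal: str) -> np.ndarray:
        """Boolean support indicator for one signal over the stacked rows."""
        parts = []
        for m in self.blocks:
            ind = np.zeros(m.p, dtype=bool)
            ind[self.support[m.dtype_tag][signal]] = True
            parts.append(ind)
        return np.concatenate(parts)


def simulate_mmds(config: SimulationConfig) -> SimulatedMMDS:
    """Generate one simulated MMDS per the configured design.

    Per block: draw p_k, pick disjoint support row sets for the step and
    random signals, fill supported rows of the signal matrix with
    amplitude x signal, add i.i.d. noise, then rescale the stacked
    signal globally so the realized SNR equals the target.  Blocks are
    returned row-centered (the standard preprocessing endpoint).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    ss1 = make_step_signal(n)
    ss2 = make_random_signal(n, rng)
    if cfg.orthogonalize_signals:
        ss2 = ss2 - (ss2 @ ss1) / (ss1 @ ss1) * ss1
        ss2 = ss2 - ss2.mean()
        ss2 = ss2 / ss2.std()
    signals = {"step": ss1, "rand": ss2}

    tags = cfg.tags()
    sig_blocks: list[np.ndarray] = []
    noise_blocks: list[np.ndarray] = []
    support: dict[str, dict[str, np.ndarray]] = {}
    for tag in tags:
        p_k = int(rng.choice(cfg.p_choices))
        m = max(int(round(cfg.support_fraction * p_k)), cfg.min_support)
        if 2 * m > p_k:
            raise ValueError(
                f"block {tag!r}: disjoint supports need 2*{m} <= p_k={p_k}"
            )
        rows = rng.choice(p_k, size=2 * m, replace=False)
        supp = {"step": np.sort(rows[:m]), "rand": np.sort(rows[m:])}
        sigma = np.zeros((p_k, n))
        for name in SIGNAL_NAMES:
            amps = rng.uniform(cfg.amplitude_low, cfg.amplitude_high, size=m)
            amps *= rng.choice([-1.0, 1.0], size=m)
            sigma[supp[name]] = np.outer(amps, signals[name])
        if cfg.noise == "gaussian":
            noise = rng.standard_normal((p_k, n))
        else:
            noise = rng.standard_t(5, size=(p_k, n))
        sig_blocks.append(sigma)
        noise_blocks.append(noise)
        support[tag] = supp

    sig_all = np.vstack(sig_blocks)
    noise_all = np.vstack(noise_blocks)
    target_ratio = 10.0 ** (cfg.snr_db / 10.0)
    scale = np.sqrt(target_ratio * np.var(noise_all) / np.var(sig_all))
    sig_blocks = [s * scale for s in sig_blocks]
    realized = snr_db(sig_all * scale, noise_all)

    blocks = []
    for tag, sigma, noise in zip(tags, sig_blocks, noise_blocks):
        vals = sigma + noise
        vals = vals - vals.mean(axis=1, keepdims=True)
        p_k = vals.shape[0]
        blocks.append(
            DataMatrix(
                values=vals,
                variable_ids=[f"{tag}_v{i:05d}" for i in range(p_k)],
                sample_ids=[f"s{j:03d}" for j in range(n)],
                dtype_tag=tag,
            )
        )
    return SimulatedMMDS(
        blocks=blocks,
        signal_blocks=sig_blocks,
        noise_blocks=noise_blocks,
        support=support,
        signals=signals,
        realized_snr_db=realized,
        config=cfg,
    )
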