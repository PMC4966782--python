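import numpy as np
import pytest

from jammit import DataMatrix, SimulationConfig, frobenius_scale, simulate_mmds, stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, tag="mRNA", prefix="v", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return DataMatrix(
        values=values,
        variable_ids=[f"{prefix}{i}" for i in range(p)],
        sample_ids=[f"{sample_prefix}{j}" for j in range(n)],
        dtype_tag=tag,
    )


@pytest.fixture
def small_planted_sim():
    """Small two-block MMDS with a strong planted pair of signals."""
    return simulate_mmds(
        SimulationConfig(p_choices=(300,), n=20, snr_db=5.0, seed=7)
    )


@pytest.fixture
def noise_supermatrix(rng):
    m = make_matrix(rng.standard_normal((400, 24)), tag="noise")
    return frobenius_scale(stack([m]))
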