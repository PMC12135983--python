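import numpy as np
import pytest

from cvsans import (ContrastSet, IntensityData, QGrid, build_design_matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_instance(seed=0, n=4, m=5, n_comp=2, sigma_range=(0.05, 0.2)):
    """Small random well-conditioned decomposition problem with known truth."""
    rng = np.random.default_rng(seed)
    qgrid = QGrid(np.sort(rng.uniform(0.01, 0.3, size=m)))
    deltas = rng.uniform(0.5, 2.5, size=(n, n_comp)) * rng.choice([-1, 1], (n, n_comp))
    contrasts = ContrastSet(tuple(f"s{i}" for i in range(n)), deltas,
                            tuple(f"c{i}" for i in range(n_comp)))
    n_pairs = n_comp * (n_comp + 1) // 2
    truth = rng.uniform(0.5, 2.0, size=(n_pairs, m))
    a = build_design_matrix(contrasts)
    sig = rng.uniform(*sigma_range, size=(n, m))
    intensities = a @ truth + rng.standard_normal((n, m)) * sig
    data = IntensityData(qgrid, intensities, sig)
    return data, contrasts, truth


@pytest.fixture
def small_instance():
    return make_instance(seed=0)
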