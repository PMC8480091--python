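import numpy as np
import pytest

from glscan.io import GLMatrix, MarkerInfo
from glscan.simulate import SimConfig, make_dataset


def make_markers(m: int) -> list[MarkerInfo]:
    return [MarkerInfo(f"chr1_{j + 1}", "0", "1", "chr1", j + 1) for j in range(m)]


def random_gl(n: int, m: int, rng: np.random.Generator) -> GLMatrix:
    """Unstructured random likelihood triples (valid but meaningless)."""
    gl = rng.uniform(0.01, 1.0, size=(n, m, 3))
    return GLMatrix(gl, make_markers(m))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two discrete populations at moderate drift, mid coverage."""
    cfg = SimConfig(n_individuals=100, n_sites=1500, n_populations=2,
                    fst=0.1, depth_mean=6, error_rate=0.01, seed=42)
    return make_dataset(cfg), cfg
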