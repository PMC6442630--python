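import numpy as np
import pytest

from twotruths.graph import Graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(n: int, p: float, rng: np.random.Generator) -> Graph:
    """Erdős–Rényi graph for structural tests."""
    upper = np.triu(rng.random((n, n)) < p, k=1)
    A = upper | upper.T
    return Graph(n=n, adjacency=A.astype(np.int8))


@pytest.fixture
def small_affinity_params():
    from twotruths.sbm import SBMParams

    return SBMParams(pi=[0.5, 0.5], B=[[0.10, 0.01], [0.01, 0.10]])


@pytest.fixture
def core_periphery_params():
    from twotruths.sbm import SBMParams

    return SBMParams(pi=[0.5, 0.5], B=[[0.25, 0.02], [0.02, 0.02]])
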