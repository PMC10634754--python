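import numpy as np
import pytest

from hypconn.connectivity import build_graph, synthetic_node_meta


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_ball_points(rng, n, dim, K=-1.0, max_rel=0.9):
    """Uniformly-directed points with norms up to max_rel of the ball radius."""
    x = rng.normal(size=(n, dim))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    radii = rng.uniform(0, max_rel, size=(n, 1)) / np.sqrt(-K)
    return x * radii


@pytest.fixture(scope="session")
def two_cluster_graph():
    """10-node graph with two tight clusters; targets are nearly binary."""
    from hypconn.synthdata import make_two_cluster_graph

    return make_two_cluster_graph(seed=3)
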