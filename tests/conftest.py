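import numpy as np
import pytest
from hypothesis import settings

import shapegraph as sg

# deterministic hypothesis runs regardless of how pytest is invoked
settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def trefoil():
    return sg.generate_trefoil(sg.TrefoilConfig(n=100, noise_sd=0.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_graph():
    """Hand-built graph: nodes A={0,1}, B={1,2}, C={3,4}; edge A-B only."""
    nodes = [
        sg.Node(0, (0,), (0, 1)),
        sg.Node(1, (1,), (1, 2)),
        sg.Node(2, (2,), (3, 4)),
    ]
    return sg.ShapeGraph(nodes, [(0, 1)], 5)


def random_shape_graph(rng, max_nodes=10, max_frames=30):
    """Random small shape graph for oracle checks (valid edges share samples)."""
    T = int(rng.integers(3, max_frames + 1))
    C = int(rng.integers(1, max_nodes + 1))
    nodes = []
    for i in range(C):
        size = int(rng.integers(1, max(2, T // 2)))
        members = tuple(sorted(rng.choice(T, size=size, replace=False)))
        nodes.append(sg.Node(i, (i,), members))
    edges = []
    for i in range(C):
        for j in range(i + 1, C):
            if set(nodes[i].members) & set(nodes[j].members) and rng.random() < 0.7:
                edges.append((i, j))
    return sg.ShapeGraph(nodes, edges, T)
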