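import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from stcar import PanelData, SpatialGraph, build_graph, lattice_graph


@pytest.fixture
def two_node_graph():
    return build_graph([("A", "B")], ["A", "B"])


@pytest.fixture
def square_lattice():
    """2 x 2 rook lattice (4 areas, 4 edges)."""
    return lattice_graph(4)


def make_panel(
    n=4, T=3, y=None, population=None, X=None, graph=None, seed=0
) -> PanelData:
    """Small panel helper with sensible fillers."""
    rng = np.random.default_rng(seed)
    if graph is None:
        graph = lattice_graph(n)
    if y is None:
        y = rng.poisson(5.0, size=(n, T))
    if population is None:
        population = np.ones((n, T))
    if X is None:
        X = np.empty((n * T, 0))
    return PanelData(
        area_ids=graph.area_ids,
        years=tuple(range(2000, 2000 + T)),
        y=np.asarray(y),
        population=population,
        X=X,
        graph=graph,
    )


def random_graph(n, p_edge, seed) -> SpatialGraph:
    """Random symmetric 0/1 graph (may contain islands)."""
    rng = np.random.default_rng(seed)
    W = np.triu((rng.random((n, n)) < p_edge).astype(float), 1)
    W = W + W.T
    ids = [f"A{k}" for k in range(n)]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SpatialGraph(tuple(ids), W)
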