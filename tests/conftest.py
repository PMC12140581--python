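import numpy as np
import pytest

from ngpa import SpatialGraph, generate_pseudoconnectome


def make_graph(n, edges, coords=None, hemisphere=None, roi=None):
    """Small explicit SpatialGraph; default coords on a line, all left."""
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    if hemisphere is None:
        hemisphere = np.array(["L"] * n, dtype=object)
    return SpatialGraph(
        node_ids=np.arange(n),
        coords=np.asarray(coords, dtype=float),
        hemisphere=np.asarray(hemisphere, dtype=object),
        edges={tuple(sorted(e)) for e in edges},
        roi=roi,
    )


def cycle_graph(n):
    return make_graph(n, [(i, (i + 1) % n) for i in range(n)])


def path_graph(n):
    return make_graph(n, [(i, i + 1) for i in range(n - 1)])


def complete_graph(n):
    return make_graph(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


def star_graph(n_leaves):
    return make_graph(n_leaves + 1, [(0, i) for i in range(1, n_leaves + 1)])


@pytest.fixture(scope="session")
def small_coords():
    return generate_pseudoconnectome(120, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
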