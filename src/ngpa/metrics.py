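"""Topological overlap, local clustering, rich-club curve, Gromov hyperbolicity."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .graphio import SpatialGraph

__all__ = [
    "topological_overlap",
    "local_clustering",
    "rich_club",
    "hyperbolicity",
    "HyperbolicityResult",
]


def topological_overlap(g: SpatialGraph) -> np.ndarray:
    """Topological overlap matrix O.

    O_ij = (C(i,j) + A_ij) / (min(k_i, k_j) + 1 - A_ij) with C(i,j) the number
    of common neighbours; O_ii := 1.  O_ij = 1 means i and j see exactly the
    same vertices, 0 means no shared neighbourhood and no direct link.
    """
    a = g.adjacency()
    k = a.sum(axis=1)
    common = a @ a
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        o = (common + a) / denom
    o[~np.isfinite(o)] = 0.0
    np.fill_diagonal(o, 1.0)
    return o


def local_clustering(g: SpatialGraph) -> np.ndarray:
    """Per-node clustering coefficient, triangles / (k choose 2); 0 for k < 2."""
    cc = nx.clustering(g.to_networkx())
    return np.array([cc[int(n)] for n in g.node_ids])


def rich_club(g: SpatialGraph) -> dict[int, float]:
    """Rich-club curve phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)).

    The subgraph at level k is induced on nodes of degree strictly greater
    than k; degenerate levels with fewer than 2 surviving nodes are omitted
    from the returned mapping.  Measures the density of the network core.
    """
    deg = {int(n): d for n, d in zip(g.node_ids, g.degrees())}
    k_max = max(deg.values()) if deg else 0
    out: dict[int, float] = {}
    for k in range(k_max + 1):
        rich = {n for n, d in deg.items() if d > k}
        n_rich = len(rich)
        if n_rich < 2:
            continue
        e_rich = sum(1 for u, v in g.edges if u in rich and v in rich)
        out[k] = 2.0 * e_rich / (n_rich * (n_rich - 1))
    return out


@dataclass
class HyperbolicityResult:
    """Four-point Gromov hyperbolicity delta(G) (smaller = more hyperbolic)."""

    delta: float
    mode: str
    n_samples: int
    seed: int | None = None
    std_error: float | None = None


def _quad_delta(d: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """delta = M1 - M2 over the three pairings, vectorized over 4-sets."""
    v1, v2, v3, v4 = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    s = np.stack(
        [
            d[v1, v2] + d[v3, v4],
            d[v1, v3] + d[v2, v4],
            d[v1, v4] + d[v2, v3],
        ],
        axis=1,
    )
    s.sort(axis=1)
    return s[:, 2] - s[:, 1]


def hyperbolicity(
    g: SpatialGraph,
    mode: str = "auto",
    n_samples: int = 100_000,
    seed: int = 0,
    max_exact_quads: int = 1_000_000,
) -> HyperbolicityResult:
    """Mean four-point hyperbolicity of a connected graph.

    For vertices (v1..v4), with S1, S2, S3 the three pairwise shortest-path
    sums, delta = M1 - M2 (difference of the two largest).  delta(G) averages
    delta over all C(N, 4) distinct 4-subsets (``exact``) or over
    ``n_samples`` uniform distinct 4-subsets (``sampled``, unbiased, with a
    reported standard error).  Trees give exactly 0.
    """
    n = g.n_nodes
    d = shortest_path(g.sparse_adjacency(), method="D", unweighted=True)
    if np.isinf(d).any():
        raise ValueError("hyperbolicity requires a connected graph")
    total = comb(n, 4) if n >= 4 else 0
    if total == 0:
        raise ValueError("need at least 4 nodes")
    if mode == "auto":
        mode = "exact" if total <= max_exact_quads else "sampled"
    if mode == "exact":
        quads = np.fromiter(
            (i for q in combinations(range(n), 4) for i in q), dtype=np.intp
        ).reshape(-1, 4)
        deltas = _quad_delta(d, quads)
        return HyperbolicityResult(
            delta=float(deltas.mean()), mode="exact", n_samples=len(quads)
        )
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    quads = np.empty((n_samples, 4), dtype=np.intp)
    filled = 0
    while filled < n_samples:
        batch = rng.integers(0, n, size=(n_samples - filled, 4))
        distinct = (
            (batch[:, 0] != batch[:, 1])
            & (batch[:, 0] != batch[:, 2])
            & (batch[:, 0] != batch[:, 3])
            & (batch[:, 1] != batch[:, 2])
            & (batch[:, 1] != batch[:, 3])
            & (batch[:, 2] != batch[:, 3])
        )
        good = batch[distinct]
        quads[filled : filled + len(good)] = good
        filled += len(good)
    deltas = _quad_delta(d, quads)
    return HyperbolicityResult(
        delta=float(deltas.mean()),
        mode="sampled",
        n_samples=n_samples,
        seed=seed,
        std_error=float(deltas.std(ddof=1) / np.sqrt(n_samples)),
    )
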