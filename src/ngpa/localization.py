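"""Eigenmode localization (IPR_q) and topologically equivalent nodes (TENs).

The inverse participation ratio IPR_q = sum_n |psi(n)|^{2q} of a unit
eigenvector distinguishes localized modes (IPR_2 -> 1) from extended ones
(IPR_2 -> 1/N).  Pairs of nodes with (near-)identical neighbourhoods — TENs —
produce scar-like localized adjacency modes: a disconnected ideal pair (u, v)
with N(u) = N(v) satisfies A(e_u - e_v) = 0, pinning an eigenvalue at 0, and
a connected ideal pair satisfies A(e_u - e_v) = -(e_u - e_v), pinning one at
-1.  These are the IPR_2 peaks observed at lambda = 0 and lambda = -1 in the
adjacency spectrum of heterogeneous networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np

from .graphio import SpatialGraph
from .spectral import EigenSystem

__all__ = [
    "IPRProfile",
    "TENRecord",
    "ipr",
    "ipr_profile",
    "jaccard_neighbors",
    "find_tens",
    "pair_difference_eigenvalue",
    "minimal_support_rotation",
]

logger = logging.getLogger(__name__)


def ipr(psi: np.ndarray, q: float) -> float:
    """IPR_q = sum_n |psi(n)|^{2q} for a unit-normalized eigenvector.

    For q > 1 the value lies in [N^{1-q}, 1]: the lower bound is attained by
    the uniform (fully extended) mode, the upper by a delta mode.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    psi = np.asarray(psi, dtype=float)
    norm = np.linalg.norm(psi)
    if abs(norm - 1.0) > 1e-8:
        psi = psi / norm
    return float(np.sum(np.abs(psi) ** (2.0 * q)))


@dataclass
class IPRProfile:
    """Per-mode IPR_q values in spectral (eigenvalue) order."""

    q: float
    eigenvalues: np.ndarray
    values: np.ndarray


def ipr_profile(es: EigenSystem, q: float = 2.0) -> IPRProfile:
    """IPR_q of every eigenvector of an eigensystem, in eigenvalue order."""
    vals = np.array([ipr(es.eigenvectors[:, i], q) for i in range(es.n)])
    return IPRProfile(q=q, eigenvalues=es.eigenvalues.copy(), values=vals)


# ---------------------------------------------------------------------------
# TEN detection
# ---------------------------------------------------------------------------

@dataclass
class TENRecord:
    """A candidate topologically-equivalent node pair."""

    pair: tuple[int, int]
    jaccard: float
    connected: bool

    @property
    def ideal(self) -> bool:
        return self.jaccard >= 1.0


def jaccard_neighbors(
    g: SpatialGraph, u: int, v: int, exclude_pair: bool = True
) -> float:
    """Jaccard index of the neighbour sets of u and v.

    With ``exclude_pair`` (default) the nodes themselves are removed from each
    other's neighbourhood first, so that an adjacent pair sharing all other
    neighbours still scores 1 — without this, a connected ideal TEN would be
    unattainable.  If both reduced sets are empty the score is 0 by
    convention (logged).
    """
    if u == v:
        raise ValueError("u and v must differ")
    nbrs = g.neighbor_map()
    return _jaccard(nbrs[u], nbrs[v], u, v, exclude_pair)


def _jaccard(
    set_u: set[int], set_v: set[int], u: int, v: int, exclude_pair: bool
) -> float:
    a, b = set_u, set_v
    if exclude_pair:
        a = a - {v}
        b = b - {u}
    union = a | b
    if not union:
        logger.debug("both neighbour sets empty for pair (%s, %s); Jaccard 0", u, v)
        return 0.0
    return len(a & b) / len(union)


def find_tens(
    g: SpatialGraph, j0: float, exclude_pair: bool = True
) -> list[TENRecord]:
    """All unordered node pairs with neighbourhood Jaccard above ``j0``.

    Candidate pairs are restricted to graph distance <= 2 (adjacent pairs plus
    pairs sharing a neighbour); any pair farther apart has Jaccard 0, so the
    pruning is exact for j0 >= 0.  Records are classified by whether the pair
    is linked by an edge (connected TENs shift the scar eigenvalue from 0 to
    -1).
    """
    if not 0.0 <= j0 <= 1.0:
        raise ValueError("j0 must lie in [0, 1]")
    nbrs = g.neighbor_map()
    candidates: set[tuple[int, int]] = set(g.edges)
    for w, around in nbrs.items():
        for u, v in combinations(sorted(around), 2):
            candidates.add((u, v))
    records = []
    for u, v in sorted(candidates):
        j = _jaccard(nbrs[u], nbrs[v], u, v, exclude_pair)
        if j > j0:
            records.append(
                TENRecord(pair=(u, v), jaccard=j, connected=(u, v) in g.edges)
            )
    return records


# ---------------------------------------------------------------------------
# scar-mode association
# ---------------------------------------------------------------------------

def pair_difference_eigenvalue(
    es: EigenSystem, u_idx: int, v_idx: int, tol: float = 1e-8
) -> Optional[float]:
    """Eigenvalue of the mode proportional to e_u - e_v, if one exists.

    The difference vector is projected onto each (possibly degenerate)
    eigenspace; if a single eigenspace carries essentially all of its norm the
    corresponding eigenvalue is returned, otherwise None.  For an ideal
    disconnected TEN pair this returns 0, for a connected ideal pair -1.
    """
    w = np.zeros(es.n)
    w[u_idx], w[v_idx] = 1.0, -1.0
    w /= np.sqrt(2.0)
    coeffs = es.eigenvectors.T @ w
    # group modes into degenerate blocks
    vals = es.eigenvalues
    blocks: list[list[int]] = [[0]]
    for i in range(1, es.n):
        if abs(vals[i] - vals[blocks[-1][0]]) < 1e-8:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    for block in blocks:
        mass = float(np.sum(coeffs[block] ** 2))
        if mass > 1.0 - tol:
            return float(np.mean(vals[block]))
    return None


def minimal_support_rotation(
    es: EigenSystem, block_indices: Iterable[int], pairs: Iterable[tuple[int, int]]
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Two-site combinations inside a degenerate eigenspace.

    IPR is basis-dependent within a degenerate block; for TEN association the
    natural basis consists of two-site vectors (e_u - e_v)/sqrt(2).  For each
    candidate node-index pair whose difference vector lies in the block's span
    (projection residual < 1e-8), the rotated in-space vector is returned.
    """
    block = list(block_indices)
    basis = es.eigenvectors[:, block]
    out = []
    for u, v in pairs:
        w = np.zeros(es.n)
        w[u], w[v] = 1.0, -1.0
        w /= np.sqrt(2.0)
        proj = basis @ (basis.T @ w)
        if np.linalg.norm(proj - w) < 1e-8:
            out.append(((u, v), proj / np.linalg.norm(proj)))
    return out
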