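"""Nonlinear geometric preferential attachment (NGPA) network growth.

A node i visiting the partially built graph links to candidate j with
probability

    p_ij  ∝  (d_j + 1)^alpha · exp(-beta · r_ij / l0)

where d_j is j's current degree, r_ij the Euclidean distance in mm, l0 the
mean-link normalizer and alpha, beta >= 0 the topological and geometric
exponents.  The +1 gives isolated vertices a nonzero attachment probability.
Growth runs separately inside each hemisphere; a small number of
interhemispheric edges is then added between uniformly chosen cross-hemisphere
pairs.  Degenerate members of the family: M(0, 0) is an Erdős–Rényi-like
graph, M(alpha, 0) a Barabási–Albert-like graph, M(0, beta) a soft random
geometric graph, and M(0, beta→∞) approaches a k-nearest-neighbour graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .graphio import SpatialGraph
from .synth import CoordinateSet

__all__ = [
    "NGPAConfig",
    "default_config",
    "attachment_weights",
    "grow_hemisphere",
    "generate_model",
]

logger = logging.getLogger(__name__)

#: fitted optimum reported for human connectomes
ALPHA_OPT = 3.0
BETA_OPT = 4.5
#: mean intrahemispheric link length of the reference connectomes, mm
L0_DEFAULT = 15.0
#: synthetic density defaults: mean degree 2E/N and interhemispheric share of E
MEAN_DEGREE_DEFAULT = 12.0
INTERHEM_FRACTION_DEFAULT = 0.02


@dataclass(frozen=True)
class NGPAConfig:
    """Growth parameters for one model draw.

    ``target_edges_per_hemisphere`` maps ``{"L": E_L, "R": E_R}``; the drawn
    per-visit link count m_i is uniform on [1, round(2 E_h / N_h)], so the
    realised edge count only approximates the target.  ``connect_policy``
    decides how a disconnected draw is repaired: ``nearest_attach`` links each
    stray component to its geometrically nearest giant-component node (the
    added edges are reported in the graph's ``meta``), ``regenerate`` redraws
    with an incremented seed.
    """

    alpha: float = ALPHA_OPT
    beta: float = BETA_OPT
    l0: float = L0_DEFAULT
    target_edges_per_hemisphere: Mapping[str, int] = None  # type: ignore[assignment]
    e_interhem: int = 1
    seed: int = 0
    connect_policy: str = "nearest_attach"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.l0 <= 0:
            raise ValueError("l0 must be positive")
        if self.e_interhem < 1:
            raise ValueError("e_interhem must be >= 1 so the graph can connect")
        if self.connect_policy not in ("nearest_attach", "regenerate"):
            raise ValueError(f"unknown connect_policy {self.connect_policy!r}")
        if self.target_edges_per_hemisphere is None:
            object.__setattr__(self, "target_edges_per_hemisphere", {})

    @property
    def r0(self) -> float:
        """Geometric cutoff scale r0 = l0 / beta (mm); inf when beta = 0."""
        return self.l0 / self.beta if self.beta > 0 else math.inf


def default_config(
    n_nodes: int,
    alpha: float = ALPHA_OPT,
    beta: float = BETA_OPT,
    mean_degree: float = MEAN_DEGREE_DEFAULT,
    interhem_fraction: float = INTERHEM_FRACTION_DEFAULT,
    l0: float = L0_DEFAULT,
    seed: int = 0,
    connect_policy: str = "nearest_attach",
) -> NGPAConfig:
    """Edge budgets from a target mean degree 2E/N split over hemispheres."""
    e_total = int(round(mean_degree * n_nodes / 2))
    e_inter = max(1, int(round(interhem_fraction * e_total)))
    e_h = (e_total - e_inter) // 2
    return NGPAConfig(
        alpha=alpha,
        beta=beta,
        l0=l0,
        target_edges_per_hemisphere={"L": e_h, "R": e_h},
        e_interhem=e_inter,
        seed=seed,
        connect_policy=connect_policy,
    )


def attachment_weights(
    degrees: np.ndarray, distances: np.ndarray, cfg: NGPAConfig
) -> np.ndarray:
    """Normalized attachment probabilities over a candidate set.

    p_j ∝ (d_j + 1)^alpha · exp(-beta r_j / l0).  If every weight underflows
    to zero the distribution falls back to uniform (logged).
    """
    degrees = np.asarray(degrees, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if degrees.size == 0:
        raise ValueError("candidate set is empty")
    if np.any(distances < 0):
        raise ValueError("distances must be nonnegative")
    w = _stable_weights(degrees, distances, cfg)
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        logger.warning("attachment weights degenerate; falling back to uniform")
        return np.full(degrees.size, 1.0 / degrees.size)
    return w / total


def _stable_weights(
    degrees: np.ndarray, distances: np.ndarray, cfg: NGPAConfig
) -> np.ndarray:
    """Unnormalized weights computed in the log domain.

    Shifting by the maximum log-weight before exponentiating leaves the
    normalized distribution unchanged but keeps large beta (or long
    distances) from underflowing every weight to zero, so the strong-penalty
    limit correctly degenerates to nearest-neighbour attachment.
    """
    with np.errstate(divide="ignore"):
        logw = cfg.alpha * np.log1p(degrees) - cfg.beta * distances / cfg.l0
    finite = np.isfinite(logw)
    if not finite.any():
        return np.zeros_like(logw)
    shifted = logw - logw[finite].max()
    return np.where(finite, np.exp(np.where(finite, shifted, 0.0)), 0.0)


def _draw_targets(
    log_weights: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw m distinct indices without replacement, p_j ∝ exp(log_weights_j).

    Uses the Gumbel-top-k construction, which is distributionally identical
    to sequential sampling with renormalization after each draw but never
    leaves the log domain, so extreme weight ratios (large beta) select the
    correct near targets instead of underflowing.
    """
    noisy = log_weights + rng.gumbel(size=log_weights.size)
    bad = ~np.isfinite(noisy)
    if bad.all():
        noisy = rng.gumbel(size=log_weights.size)  # degenerate: uniform
    elif bad.any():
        noisy[bad] = -np.inf
    if m >= noisy.size:
        return np.argsort(noisy)[::-1]
    top = np.argpartition(noisy, -m)[-m:]
    return top


def grow_hemisphere(
    coords: np.ndarray,
    cfg: NGPAConfig,
    rng: np.random.Generator,
    target_edges: Optional[int] = None,
) -> set[tuple[int, int]]:
    """Grow one hemisphere's edge set over ``coords`` (local indices 0..N_h-1).

    Nodes are visited once each in random order.  A visit of node i draws
    m_i ~ UniformInt[1, round(2 E_h / N_h)] and links i to m_i distinct
    targets sampled sequentially with :func:`attachment_weights` over all
    hemisphere nodes except i and i's existing neighbours.  Degrees are
    snapshotted at the start of each visit.  Double connections never occur,
    so the result is a simple graph with approximately E_h edges.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("a hemisphere needs at least 2 nodes")
    if target_edges is None:
        target_edges = max(n // 2, 1)
    m_max = max(1, int(round(2 * target_edges / n)))
    dist = cdist(coords, coords)
    degrees = np.zeros(n, dtype=float)
    nbrs: list[set[int]] = [set() for _ in range(n)]
    edges: set[tuple[int, int]] = set()
    order = rng.permutation(n)
    for i in order:
        m_i = int(rng.integers(1, m_max + 1))
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if nbrs[i]:
            mask[list(nbrs[i])] = False
        cand = np.flatnonzero(mask)
        if cand.size == 0:
            continue
        if m_i > cand.size:
            logger.debug("clamping m_i=%d to %d candidates", m_i, cand.size)
            m_i = cand.size
        with np.errstate(divide="ignore"):
            logw = (
                cfg.alpha * np.log1p(degrees[cand])
                - cfg.beta * dist[i, cand] / cfg.l0
            )
        picks = _draw_targets(logw, m_i, rng)
        for p in picks:
            j = int(cand[p])
            edges.add((i, j) if i < j else (j, i))
            nbrs[i].add(j)
            nbrs[j].add(int(i))
        # snapshot semantics: degrees update only after the visit completes
        for p in picks:
            j = int(cand[p])
            degrees[j] += 1
        degrees[i] += len(picks)
    return edges


def _connect_nearest(
    edges: set[tuple[int, int]], coords: np.ndarray, n: int
) -> list[tuple[int, int]]:
    """Link every stray component to the geometrically nearest giant node."""
    added: list[tuple[int, int]] = []
    while True:
        if edges:
            rows = [u for u, v in edges] + [v for u, v in edges]
            cols = [v for u, v in edges] + [u for u, v in edges]
            adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        else:
            adj = csr_matrix((n, n))
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp == 1:
            return added
        giant = int(np.argmax(np.bincount(labels)))
        stray_label = next(l for l in range(n_comp) if l != giant)
        stray = np.flatnonzero(labels == stray_label)
        main = np.flatnonzero(labels == giant)
        d = cdist(coords[stray], coords[main])
        k = int(np.argmin(d))
        u = int(stray[k // len(main)])
        v = int(main[k % len(main)])
        e = (u, v) if u < v else (v, u)
        edges.add(e)
        added.append(e)


def generate_model(coords: CoordinateSet, cfg: NGPAConfig) -> SpatialGraph:
    """Grow the full two-hemisphere model M(alpha, beta) on a coordinate set.

    Each hemisphere is grown independently, then ``cfg.e_interhem`` edges are
    added between uniformly chosen cross-hemisphere pairs (no duplicates).
    The returned graph is connected; any repair edges required by
    ``connect_policy='nearest_attach'`` are listed in ``meta['repair_edges']``
    and are not counted as interhemispheric budget edges.
    """
    masks = {h: np.flatnonzero(coords.mask(h)) for h in ("L", "R")}
    if any(len(m) == 0 for m in masks.values()):
        raise ValueError("both hemispheres must be nonempty")
    n_l, n_r = len(masks["L"]), len(masks["R"])
    if cfg.e_interhem > n_l * n_r:
        raise ValueError("e_interhem exceeds the number of cross-hemisphere pairs")

    seed = cfg.seed
    for attempt in range(100):
        rng = np.random.default_rng(seed)
        edges: set[tuple[int, int]] = set()
        for hemi in ("L", "R"):
            local = masks[hemi]
            target = cfg.target_edges_per_hemisphere.get(hemi) if cfg.target_edges_per_hemisphere else None
            local_edges = grow_hemisphere(
                coords.coords[local], cfg, rng, target_edges=target
            )
            for u, v in local_edges:
                gu, gv = int(local[u]), int(local[v])
                edges.add((gu, gv) if gu < gv else (gv, gu))
        inter: set[tuple[int, int]] = set()
        while len(inter) < cfg.e_interhem:
            u = int(masks["L"][rng.integers(n_l)])
            v = int(masks["R"][rng.integers(n_r)])
            inter.add((u, v) if u < v else (v, u))
        edges |= inter

        repair: list[tuple[int, int]] = []
        if cfg.connect_policy == "nearest_attach":
            repair = _connect_nearest(edges, coords.coords, coords.n_nodes)
        else:  # regenerate
            rows = [u for u, v in edges] + [v for u, v in edges]
            cols = [v for u, v in edges] + [u for u, v in edges]
            adj = csr_matrix(
                (np.ones(len(rows)), (rows, cols)),
                shape=(coords.n_nodes, coords.n_nodes),
            )
            n_comp, _ = connected_components(adj, directed=False)
            if n_comp > 1:
                seed += 1
                continue
        return SpatialGraph(
            node_ids=np.arange(coords.n_nodes),
            coords=coords.coords,
            hemisphere=coords.hemisphere,
            edges=edges,
            roi=coords.roi,
            meta={
                "alpha": cfg.alpha,
                "beta": cfg.beta,
                "l0": cfg.l0,
                "seed": seed,
                "e_interhem": cfg.e_interhem,
                "repair_edges": repair,
            },
        )
    raise RuntimeError("could not generate a connected graph in 100 attempts")
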