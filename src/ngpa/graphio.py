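"""Spatial graph container, file I/O and preprocessing.

Graphs are simple, undirected and binary; every node carries 3-D millimetre
coordinates, a hemisphere label in {L, R}, and optionally an integer region
(ROI) label.  Two on-disk representations are supported:

* GraphML (via networkx), with configurable attribute names;
* a two-file TSV dialect: a node table with columns
  ``id  x  y  z  hemisphere  [roi]`` and an edge list with columns
  ``id_u  id_v``, both with a header row.  Lines starting with ``#`` are
  provenance comments and are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SpatialGraph",
    "FormatError",
    "CoverageError",
    "load_spatial_graph",
    "save_spatial_graph",
    "preprocess",
    "edge_lengths",
    "mean_edge_length",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates the spatial-graph contract."""


class CoverageError(ValueError):
    """Raised when the largest connected component is too small a fraction."""


@dataclass
class SpatialGraph:
    """Simple undirected binary graph embedded in 3-D space.

    Parameters
    ----------
    node_ids : integer node identifiers, one per node.
    coords : (N, 3) array of millimetre coordinates.
    hemisphere : per-node label, each ``"L"`` or ``"R"``.
    roi : optional per-node integer region label.
    edges : set of unordered node-id pairs stored as sorted tuples.
    original_ids : mapping back to pre-preprocessing identifiers (parallel to
        ``node_ids``); ``None`` for freshly constructed graphs.
    meta : free-form provenance (e.g. repair edges added to connect the graph).
    """

    node_ids: np.ndarray
    coords: np.ndarray
    hemisphere: np.ndarray
    edges: set[tuple[int, int]]
    roi: Optional[np.ndarray] = None
    original_ids: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=int)
        self.edges = {self._canon(u, v) for (u, v) in self.edges if u != v}
        known = set(self.node_ids.tolist())
        for u, v in self.edges:
            if u not in known or v not in known:
                raise FormatError(f"edge ({u}, {v}) references an unknown node")
        if self.coords.shape != (self.n_nodes, 3):
            raise FormatError(
                f"coords must be (N, 3); got {self.coords.shape} for N={self.n_nodes}"
            )
        bad = {h for h in self.hemisphere} - {"L", "R"}
        if bad:
            raise FormatError(f"hemisphere labels must be L or R; got {sorted(bad)}")

    @staticmethod
    def _canon(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self) -> dict[int, int]:
        """Map node id -> positional index."""
        return {int(nid): i for i, nid in enumerate(self.node_ids)}

    def adjacency(self) -> np.ndarray:
        """Dense symmetric binary adjacency matrix in node order."""
        idx = self.index_of()
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            i, j = idx[u], idx[v]
            a[i, j] = a[j, i] = 1.0
        return a

    def sparse_adjacency(self) -> csr_matrix:
        idx = self.index_of()
        if not self.edges:
            return csr_matrix((self.n_nodes, self.n_nodes))
        rows, cols = [], []
        for u, v in self.edges:
            i, j = idx[u], idx[v]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes))

    def degrees(self) -> np.ndarray:
        idx = self.index_of()
        d = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            d[idx[u]] += 1
            d[idx[v]] += 1
        return d

    def neighbors(self, u: int) -> set[int]:
        return {w if x == u else x for (x, w) in self.edges if u in (x, w)}

    def neighbor_map(self) -> dict[int, set[int]]:
        nbrs: dict[int, set[int]] = {int(n): set() for n in self.node_ids}
        for u, v in self.edges:
            nbrs[u].add(v)
            nbrs[v].add(u)
        return nbrs

    def interhemispheric_edges(self) -> set[tuple[int, int]]:
        hemi = {int(n): h for n, h in zip(self.node_ids, self.hemisphere)}
        return {(u, v) for (u, v) in self.edges if hemi[u] != hemi[v]}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, nid in enumerate(self.node_ids):
            attrs = dict(
                x=float(self.coords[i, 0]),
                y=float(self.coords[i, 1]),
                z=float(self.coords[i, 2]),
                hemisphere=str(self.hemisphere[i]),
            )
            if self.roi is not None:
                attrs["roi"] = int(self.roi[i])
            g.add_node(int(nid), **attrs)
        g.add_edges_from(self.edges)
        return g

    def copy(self) -> "SpatialGraph":
        return SpatialGraph(
            node_ids=self.node_ids.copy(),
            coords=self.coords.copy(),
            hemisphere=self.hemisphere.copy(),
            edges=set(self.edges),
            roi=None if self.roi is None else self.roi.copy(),
            original_ids=None if self.original_ids is None else self.original_ids.copy(),
            meta=dict(self.meta),
        )

    def __eq__(self, other) -> bool:  # structural equality for round trips
        if not isinstance(other, SpatialGraph):
            return NotImplemented
        same_roi = (self.roi is None) == (other.roi is None) and (
            self.roi is None or np.array_equal(self.roi, other.roi)
        )
        return (
            np.array_equal(self.node_ids, other.node_ids)
            and np.allclose(self.coords, other.coords)
            and np.array_equal(self.hemisphere, other.hemisphere)
            and self.edges == other.edges
            and same_roi
        )


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def _node_table_paths(path: Path) -> tuple[Path, Path]:
    """TSV dialect stores nodes at <stem>.nodes.tsv and edges at <stem>.edges.tsv."""
    p = Path(path)
    stem = str(p)
    for suffix in (".nodes.tsv", ".edges.tsv", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return Path(stem + ".nodes.tsv"), Path(stem + ".edges.tsv")


def load_spatial_graph(
    path,
    format: str = "auto",
    hemisphere_attr: str = "hemisphere",
) -> SpatialGraph:
    """Read a spatial graph from GraphML or the TSV node-table dialect.

    Edge weights, if present in the file, are discarded: the returned graph is
    binary.  For GraphML, hemisphere labels are taken from ``hemisphere_attr``;
    if the attribute is absent they fall back to the sign of the x coordinate
    (x < 0 is L), which is logged.
    """
    path = Path(path)
    if format == "auto":
        format = "graphml" if path.suffix == ".graphml" else "tsv"
    if format == "graphml":
        return _load_graphml(path, hemisphere_attr)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown format {format!r}; expected 'graphml' or 'tsv'")


def _load_graphml(path: Path, hemisphere_attr: str) -> SpatialGraph:
    if not path.exists():
        raise FileNotFoundError(path)
    g = nx.read_graphml(path)
    node_order = list(g.nodes())
    coords = np.zeros((len(node_order), 3))
    hemis = []
    rois = []
    have_roi = all("roi" in g.nodes[n] for n in node_order)
    fallback_used = False
    for i, n in enumerate(node_order):
        attrs = g.nodes[n]
        for k, axis in zip("xyz", range(3)):
            if k not in attrs:
                raise FormatError(f"node {n!r} is missing coordinate attribute {k!r}")
            coords[i, axis] = float(attrs[k])
        if hemisphere_attr in attrs:
            hemis.append(str(attrs[hemisphere_attr]))
        else:
            fallback_used = True
            hemis.append("L" if coords[i, 0] < 0 else "R")
        if have_roi:
            rois.append(int(attrs["roi"]))
    if fallback_used:
        logger.info(
            "hemisphere attribute %r absent; derived labels from sign(x)",
            hemisphere_attr,
        )
    ids = {n: i for i, n in enumerate(node_order)}
    edges = {
        SpatialGraph._canon(ids[u], ids[v]) for u, v in g.edges() if ids[u] != ids[v]
    }
    return SpatialGraph(
        node_ids=np.arange(len(node_order)),
        coords=coords,
        hemisphere=np.array(hemis, dtype=object),
        edges=edges,
        roi=np.array(rois, dtype=int) if have_roi else None,
    )


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _load_tsv(path: Path) -> SpatialGraph:
    nodes_path, edges_path = _node_table_paths(path)
    if not nodes_path.exists():
        raise FileNotFoundError(nodes_path)
    nodes = _read_tsv(nodes_path)
    for col in ("id", "x", "y", "z", "hemisphere"):
        if col not in nodes.columns:
            raise FormatError(f"node table {nodes_path} is missing column {col!r}")
    edges_df = _read_tsv(edges_path) if edges_path.exists() else pd.DataFrame(
        columns=["id_u", "id_v"]
    )
    edges = {
        SpatialGraph._canon(int(u), int(v))
        for u, v in zip(edges_df["id_u"], edges_df["id_v"])
        if int(u) != int(v)
    }
    roi = nodes["roi"].to_numpy(dtype=int) if "roi" in nodes.columns else None
    return SpatialGraph(
        node_ids=nodes["id"].to_numpy(dtype=int),
        coords=nodes[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=nodes["hemisphere"].to_numpy(dtype=object),
        edges=edges,
        roi=roi,
    )


def save_spatial_graph(g: SpatialGraph, path, format: str = "auto",
                       provenance: str = "") -> None:
    """Write a spatial graph as GraphML or the TSV dialect."""
    path = Path(path)
    if format == "auto":
        format = "graphml" if path.suffix == ".graphml" else "tsv"
    if format == "graphml":
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(g.to_networkx(), path)
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    nodes_path, edges_path = _node_table_paths(path)
    nodes_path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# ngpa spatial graph{(' — ' + provenance) if provenance else ''}\n"
    cols = {
        "id": g.node_ids,
        "x": g.coords[:, 0],
        "y": g.coords[:, 1],
        "z": g.coords[:, 2],
        "hemisphere": g.hemisphere,
    }
    if g.roi is not None:
        cols["roi"] = g.roi
    with open(nodes_path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)
    with open(edges_path, "w") as fh:
        fh.write(header)
        pd.DataFrame(sorted(g.edges), columns=["id_u", "id_v"]).to_csv(
            fh, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(g: SpatialGraph, min_coverage: float = 0.75) -> SpatialGraph:
    """Enforce the analysis contract: simple, connected, no isolated nodes.

    Self-loops are dropped, then isolated nodes, then only the largest
    connected component is kept.  If that component covers less than
    ``min_coverage`` of the (original) nodes the graph is rejected with
    :class:`CoverageError`.  Surviving nodes are re-indexed ``0..N-1``; the
    original identifiers are retained in ``original_ids``.
    """
    n_before = g.n_nodes
    edges = {e for e in g.edges if e[0] != e[1]}
    deg: dict[int, int] = {int(n): 0 for n in g.node_ids}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    keep = [n for n in g.node_ids if deg[int(n)] > 0]
    if not keep:
        raise CoverageError("graph has no edges after self-loop removal")
    idx = {int(n): i for i, n in enumerate(keep)}
    adj = csr_matrix(
        (
            np.ones(2 * len(edges)),
            (
                [idx[u] for u, v in edges] + [idx[v] for u, v in edges],
                [idx[v] for u, v in edges] + [idx[u] for u, v in edges],
            ),
        ),
        shape=(len(keep), len(keep)),
    )
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    giant = int(np.argmax(sizes))
    coverage = sizes[giant] / n_before
    if coverage < min_coverage:
        raise CoverageError(
            f"largest component covers {coverage:.2f} < {min_coverage:.2f} of nodes"
        )
    surviving = [n for n in keep if labels[idx[int(n)]] == giant]
    pos = {int(n): g.index_of()[int(n)] for n in surviving}
    remap = {int(n): i for i, n in enumerate(surviving)}
    new_edges = {
        SpatialGraph._canon(remap[u], remap[v])
        for u, v in edges
        if u in remap and v in remap
    }
    rows = [pos[int(n)] for n in surviving]
    orig = g.original_ids if g.original_ids is not None else g.node_ids
    return SpatialGraph(
        node_ids=np.arange(len(surviving)),
        coords=g.coords[rows],
        hemisphere=g.hemisphere[rows],
        edges=new_edges,
        roi=None if g.roi is None else g.roi[rows],
        original_ids=np.asarray([orig[pos[int(n)]] for n in surviving]),
        meta=dict(g.meta),
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def edge_lengths(g: SpatialGraph, include_interhemispheric: bool = False) -> np.ndarray:
    """Euclidean length (mm) of each retained edge.

    Interhemispheric edges are excluded by default: only connections within
    each hemisphere enter the edge-length statistics.
    """
    idx = g.index_of()
    hemi = {int(n): h for n, h in zip(g.node_ids, g.hemisphere)}
    out = []
    for u, v in sorted(g.edges):
        if not include_interhemispheric and hemi[u] != hemi[v]:
            continue
        out.append(float(np.linalg.norm(g.coords[idx[u]] - g.coords[idx[v]])))
    return np.asarray(out)


def mean_edge_length(g: SpatialGraph) -> float:
    """Mean intrahemispheric edge length l0 = <r_ij> in millimetres."""
    lengths = edge_lengths(g)
    return float(lengths.mean()) if lengths.size else float("nan")
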