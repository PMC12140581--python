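"""Synthetic "pseudoconnectome" coordinate sets.

Real structural connectomes provide node coordinates from anatomical
parcellations.  The pseudoconnectome emulation replaces them with uniformly
random positions inside two disjoint hemisphere volumes — spectra and
edge-length distributions of networks grown on such coordinates are close to
those grown on real coordinates, so every downstream stage can be exercised
without external data.

The default geometry is two axis-aligned boxes of 65 x 140 x 110 mm (roughly
human-hemisphere extents) separated by a 4 mm midline gap; only uniformity
within each hemisphere matters for the statistics, the extents are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "HemisphereBoxes",
    "CoordinateSet",
    "GeometryError",
    "generate_pseudoconnectome",
    "assign_rois",
    "generate_multiscale_family",
]


class GeometryError(ValueError):
    """Raised when the two hemisphere volumes overlap."""


@dataclass(frozen=True)
class HemisphereBoxes:
    """Two axis-aligned hemisphere boxes split along x with a midline gap.

    ``extent`` is the (dx, dy, dz) size of each box in mm; ``gap`` the distance
    between the boxes' facing x-walls.  The left box occupies
    x in [-gap/2 - dx, -gap/2], the right box x in [gap/2, gap/2 + dx]; y and z
    are centred on 0.
    """

    extent: tuple[float, float, float] = (65.0, 140.0, 110.0)
    gap: float = 4.0

    def __post_init__(self) -> None:
        if self.gap <= 0 or any(e <= 0 for e in self.extent):
            raise GeometryError("hemisphere boxes must be disjoint with positive size")

    def bounds(self, hemisphere: str) -> np.ndarray:
        """(2, 3) array of [low, high] bounds for one hemisphere box."""
        dx, dy, dz = self.extent
        if hemisphere == "L":
            xlo, xhi = -self.gap / 2 - dx, -self.gap / 2
        elif hemisphere == "R":
            xlo, xhi = self.gap / 2, self.gap / 2 + dx
        else:
            raise ValueError(f"hemisphere must be L or R, got {hemisphere!r}")
        return np.array([[xlo, -dy / 2, -dz / 2], [xhi, dy / 2, dz / 2]])

    def contains(self, coords: np.ndarray, hemisphere: str) -> np.ndarray:
        lo, hi = self.bounds(hemisphere)
        c = np.atleast_2d(coords)
        return np.all((c >= lo) & (c <= hi), axis=1)


@dataclass
class CoordinateSet:
    """Per-node coordinates, hemisphere labels and optional ROI labels."""

    coords: np.ndarray
    hemisphere: np.ndarray
    roi: Optional[np.ndarray] = None
    scale_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.hemisphere)

    def mask(self, hemisphere: str) -> np.ndarray:
        return self.hemisphere == hemisphere


def generate_pseudoconnectome(
    n_nodes: int,
    geometry: HemisphereBoxes = HemisphereBoxes(),
    seed: int = 0,
) -> CoordinateSet:
    """Draw ``n_nodes`` uniform positions, split between the two hemispheres.

    ceil(n/2) nodes go to the left box and floor(n/2) to the right, each
    uniform within its box.  Deterministic for a fixed seed.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes (one per hemisphere)")
    rng = np.random.default_rng(seed)
    n_left = (n_nodes + 1) // 2
    n_right = n_nodes - n_left
    parts, labels = [], []
    for hemi, n in (("L", n_left), ("R", n_right)):
        lo, hi = geometry.bounds(hemi)
        parts.append(rng.uniform(lo, hi, size=(n, 3)))
        labels += [hemi] * n
    return CoordinateSet(
        coords=np.vstack(parts), hemisphere=np.array(labels, dtype=object)
    )


def _split_k(k: int, n_left: int, n_right: int) -> tuple[int, int]:
    """Split k ROIs between hemispheres proportionally to node counts."""
    k_left = int(round(k * n_left / (n_left + n_right)))
    k_left = min(max(k_left, 1), k - 1) if k >= 2 else k
    return k_left, k - k_left


def assign_rois(cs: CoordinateSet, k: int = 87, seed: int = 0) -> CoordinateSet:
    """Partition nodes into ``k`` spatially coherent regions.

    Hemispheres are clustered separately (no ROI straddles the midline) with
    seeded k-means on the coordinates, so labels are deterministic for a fixed
    seed and every ROI is nonempty.  Labels 0..k_L-1 are left-hemisphere,
    k_L..k-1 right-hemisphere.
    """
    if k > cs.n_nodes:
        raise ValueError(f"k={k} exceeds the number of nodes {cs.n_nodes}")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_left = int(np.sum(cs.mask("L")))
    n_right = cs.n_nodes - n_left
    k_left, k_right = _split_k(k, n_left, n_right)
    roi = np.empty(cs.n_nodes, dtype=int)
    offset = 0
    for hemi, k_h in (("L", k_left), ("R", k_right)):
        m = cs.mask(hemi)
        pts = cs.coords[m]
        if k_h >= len(pts):
            labels = np.arange(len(pts))
        else:
            km = KMeans(n_clusters=k_h, n_init=4, random_state=seed)
            labels = km.fit_predict(pts)
        roi[m] = labels + offset
        offset += int(labels.max()) + 1
    return replace(cs, roi=roi)


def _representatives(pts: np.ndarray, n_coarse: int, seed: int) -> np.ndarray:
    """Indices of ``n_coarse`` cluster-representative points of ``pts``.

    Points are k-means clustered and, per cluster, the point nearest the
    centroid is the representative at the coarser scale.
    """
    if n_coarse >= len(pts):
        return np.arange(len(pts))
    km = KMeans(n_clusters=n_coarse, n_init=4, random_state=seed)
    labels = km.fit_predict(pts)
    reps = np.empty(n_coarse, dtype=int)
    for c in range(n_coarse):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(pts[members] - km.cluster_centers_[c], axis=1)
        reps[c] = members[np.argmin(d)]
    return reps


def generate_multiscale_family(
    n_base: int,
    n_scales: int,
    geometry: HemisphereBoxes = HemisphereBoxes(),
    seed: int = 0,
    k_roi: int = 87,
) -> list[CoordinateSet]:
    """Nested coordinate sets of sizes n_base, 2 n_base, ..., 2^(S-1) n_base.

    The finest scale is a fresh pseudoconnectome; each coarser scale keeps one
    representative node per spatial cluster of the next finer scale
    (hemispheres balanced).  ROIs are assigned once at the finest scale and
    inherited by representatives, so ROI projections are comparable across
    scales.  Returned coarsest-first; ``scale_id`` is 0 for the coarsest.
    """
    if n_scales < 2:
        raise ValueError("need at least 2 scales")
    sizes = [n_base * 2**s for s in range(n_scales)]
    finest = generate_pseudoconnectome(sizes[-1], geometry=geometry, seed=seed)
    finest = assign_rois(finest, k=min(k_roi, sizes[0]), seed=seed)
    finest.scale_id = n_scales - 1
    family = [finest]
    current = finest
    for s in range(n_scales - 2, -1, -1):
        n_target = sizes[s]
        m_left = np.flatnonzero(current.mask("L"))
        m_right = np.flatnonzero(current.mask("R"))
        n_l = min((n_target + 1) // 2, len(m_left))
        n_r = n_target - n_l
        keep_parts = []
        for m, n_h in ((m_left, n_l), (m_right, n_r)):
            reps = _representatives(current.coords[m], n_h, seed=seed + 1000 + s)
            keep_parts.append(m[reps])
        keep = np.concatenate(keep_parts)
        coarse = CoordinateSet(
            coords=current.coords[keep],
            hemisphere=current.hemisphere[keep],
            roi=current.roi[keep],
            scale_id=s,
        )
        family.append(coarse)
        current = coarse
    family.reverse()
    return family
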