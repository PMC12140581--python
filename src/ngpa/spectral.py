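"""Graph matrices, eigensystems, spectral density and return probability.

The three matrices used throughout are the adjacency matrix A, the Laplacian
L = D - A and the normalized Laplacian L^norm = D^{-1/2} L D^{-1/2}.  For a
connected graph both Laplacians are positive semidefinite with a single zero
eigenvalue, and the normalized spectrum lies in [0, 2] so that networks of
different sizes can be compared on a common support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.stats import wasserstein_distance

from .graphio import SpatialGraph

__all__ = [
    "EigenSystem",
    "build_matrix",
    "eigensystem",
    "graph_eigensystem",
    "spectral_density",
    "count_soft_modes",
    "return_probability",
    "fit_return_exponent",
    "PowerLawFit",
    "emd_1d",
]

MATRIX_KINDS = ("adjacency", "laplacian", "normalized_laplacian")

#: isolated cluster ("soft") modes of the normalized Laplacian sit below this
SOFT_MODE_THRESHOLD = 0.15


@dataclass
class EigenSystem:
    """Full ordered spectrum of one graph matrix.

    ``eigenvalues`` ascend; ``eigenvectors[:, i]`` is the unit eigenvector of
    ``eigenvalues[i]``.
    """

    kind: str
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    def mode(self, i: int) -> np.ndarray:
        return self.eigenvectors[:, i]


def build_matrix(g: SpatialGraph, kind: str) -> np.ndarray:
    """Dense adjacency, Laplacian or normalized Laplacian of a spatial graph."""
    if kind not in MATRIX_KINDS:
        raise ValueError(f"kind must be one of {MATRIX_KINDS}, got {kind!r}")
    a = g.adjacency()
    if kind == "adjacency":
        return a
    deg = a.sum(axis=1)
    lap = np.diag(deg) - a
    if kind == "laplacian":
        return lap
    if np.any(deg == 0):
        raise ValueError("normalized Laplacian undefined for degree-0 nodes")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return lap * inv_sqrt[:, None] * inv_sqrt[None, :]


def eigensystem(m: np.ndarray, kind: str = "generic") -> EigenSystem:
    """Full eigendecomposition of a symmetric matrix, ascending order."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    vals, vecs = eigh(m)
    return EigenSystem(kind=kind, eigenvalues=vals, eigenvectors=vecs)


def graph_eigensystem(g: SpatialGraph, kind: str) -> EigenSystem:
    """Eigensystem of a chosen graph matrix (convenience wrapper)."""
    return eigensystem(build_matrix(g, kind), kind=kind)


def graph_eigenvalues(g: SpatialGraph, kind: str) -> np.ndarray:
    """Eigenvalues only — cheaper when eigenvectors are not needed."""
    m = build_matrix(g, kind)
    return eigh(m, eigvals_only=True)


def spectral_density(
    eigenvalues: np.ndarray | Sequence[float],
    bin_edges: np.ndarray,
) -> np.ndarray:
    """Histogram estimate of rho(lambda) = (1/N) sum_i delta(lambda - lambda_i).

    Normalized so the histogram integrates to 1 over the binned range.  If an
    eigenvalue falls outside ``bin_edges`` the range is extended with a
    warning-sized pair of outer bins rather than silently dropping mass.
    """
    vals = np.asarray(eigenvalues, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one eigenvalue")
    edges = np.asarray(bin_edges, dtype=float)
    if vals.min() < edges[0] or vals.max() > edges[-1]:
        import warnings

        warnings.warn(
            "eigenvalues outside bin range; extending range", stacklevel=2
        )
        lo = min(edges[0], vals.min())
        hi = max(edges[-1], vals.max())
        edges = np.concatenate([[lo], edges[(edges > lo) & (edges < hi)], [hi]])
    density, _ = np.histogram(vals, bins=edges, density=True)
    return density


def ensemble_spectral_density(
    spectra: Sequence[np.ndarray], bin_edges: np.ndarray
) -> np.ndarray:
    """Average of per-graph spectral densities over an ensemble."""
    return np.mean([spectral_density(s, bin_edges) for s in spectra], axis=0)


def count_soft_modes(
    es: EigenSystem | np.ndarray, threshold: float = SOFT_MODE_THRESHOLD
) -> int:
    """Number of nontrivial isolated cluster modes (lambda < threshold).

    The trivial lambda_1 = 0 mode of a connected graph is excluded, so a graph
    with no cluster structure reports 0.
    """
    vals = es.eigenvalues if isinstance(es, EigenSystem) else np.asarray(es)
    vals = np.sort(vals)
    return int(np.sum(vals[1:] < threshold))


def return_probability(
    laplacian_eigenvalues: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """Diffusion return probability R(t) = (1/N) sum_i exp(-t lambda_i^lap).

    Expects eigenvalues of the unnormalized Laplacian.  R(0) = 1 and R decays
    to (#components)/N as t -> inf.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    lam = np.asarray(laplacian_eigenvalues, dtype=float)
    return np.exp(-np.outer(t, lam)).mean(axis=1)


@dataclass
class PowerLawFit:
    """Result of a sliding-window power-law fit R(t) ~ t^-xi."""

    xi: Optional[float]
    window: Optional[tuple[float, float]]
    r2: Optional[float]

    @property
    def is_power_law(self) -> bool:
        return self.xi is not None


def fit_return_exponent(
    t_grid: np.ndarray,
    r_curve: np.ndarray,
    min_decade: float = 1.0,
    r2_min: float = 0.9,
    xi_floor: float = 0.05,
    asymptote: float | None = None,
) -> PowerLawFit:
    """Best power-law window of a return-probability curve.

    Scans all contiguous windows of log-spaced ``t_grid`` spanning at least
    ``min_decade`` decades, fits log R against log t by least squares, and
    keeps the window with the highest R^2.  Windows with R^2 < ``r2_min`` or
    a fitted exponent below ``xi_floor`` (flat curve) are rejected; if none
    survives the result carries ``xi=None`` rather than raising.

    ``asymptote`` subtracts a known finite-size limit R(inf) before fitting
    (for a connected graph R(inf) = 1/N exactly).  R(t) saturates at that
    constant, so the raw curve cannot follow a power law near the plateau;
    removing the limit keeps the saturation shoulder from being mistaken for
    a scaling window.
    """
    t = np.asarray(t_grid, dtype=float)
    r = np.asarray(r_curve, dtype=float)
    if asymptote is not None:
        r = r - float(asymptote)
    ok = (t > 0) & (r > 0)
    t, r = t[ok], r[ok]
    if t.size < 10 or np.log10(t.max() / t.min()) < 2:
        raise ValueError("need >= 10 positive t points spanning >= 2 decades")
    logt, logr = np.log10(t), np.log10(r)
    best: tuple[float, float, tuple[float, float]] | None = None
    n = t.size
    for i in range(n):
        for j in range(i + 4, n):
            if logt[j] - logt[i] < min_decade:
                continue
            x, y = logt[i : j + 1], logr[i : j + 1]
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
            xi = -slope
            if xi < xi_floor or r2 < r2_min:
                continue
            if best is None or r2 > best[0]:
                best = (r2, xi, (t[i], t[j]))
    if best is None:
        return PowerLawFit(xi=None, window=None, r2=None)
    r2, xi, window = best
    return PowerLawFit(xi=float(xi), window=window, r2=float(r2))


def emd_1d(samples_a, samples_b) -> float:
    """Earth mover's (Wasserstein-1) distance between two empirical samples.

    Equals the area between the two empirical CDFs; a true metric on
    distributions, insensitive to support discontinuities.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(wasserstein_distance(a, b))
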