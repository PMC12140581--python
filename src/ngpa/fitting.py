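"""Two-stage EMD parameter selection and the interhemispheric cut experiment.

Stage 1 tunes the geometric penalty: for each candidate alpha, the beta
minimizing the earth mover's distance between the model's pooled
intrahemispheric edge-length distribution and a reference one is selected.
Stage 2 then picks the alpha whose model M(alpha, beta_opt(alpha)) minimizes
the EMD between normalized-Laplacian spectral densities.  Fitting only edge
lengths first keeps the search one-dimensional per alpha and guarantees the
chosen model is geometrically consistent with the reference before spectra
are compared.

The cut experiment probes cluster-mode coupling: interhemispheric edges are
progressively removed and the low normalized-Laplacian eigenvalues
(lambda_2, lambda_3, lambda_4) tracked.  lambda_2 approximately counts the
interhemispheric links and must reach 0 at full cut; the size of the induced
change in lambda_3 and lambda_4 measures how strongly the intra-hemisphere
cluster modes are coupled to the hemisphere partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import eigh

from .generator import NGPAConfig, default_config, generate_model
from .graphio import SpatialGraph, edge_lengths
from .spectral import build_matrix, emd_1d
from .synth import CoordinateSet

__all__ = [
    "FitResult",
    "CutTrajectory",
    "stage1_fit_beta",
    "stage2_fit_alpha",
    "fit_ngpa",
    "remove_interhemispheric",
    "cut_experiment",
    "ALPHA_GRID_DEFAULT",
    "BETA_GRID_DEFAULT",
]

#: full search grids; tests and examples use reduced spans for speed
ALPHA_GRID_DEFAULT = tuple(np.arange(0.0, 5.0 + 1e-9, 0.5))
BETA_GRID_DEFAULT = tuple(np.round(np.arange(0.0, 8.0 + 1e-9, 0.1), 10))


def _model_config(
    coords: CoordinateSet,
    alpha: float,
    beta: float,
    mean_degree: float,
    l0: float,
    seed: int,
) -> NGPAConfig:
    return default_config(
        n_nodes=coords.n_nodes,
        alpha=alpha,
        beta=beta,
        mean_degree=mean_degree,
        l0=l0,
        seed=seed,
    )


def _pooled_lengths(
    coords: CoordinateSet,
    alpha: float,
    beta: float,
    n_reps: int,
    seed: int,
    mean_degree: float,
    l0: float,
) -> np.ndarray:
    pools = []
    for rep in range(n_reps):
        cfg = _model_config(coords, alpha, beta, mean_degree, l0, seed + rep)
        g = generate_model(coords, cfg)
        pools.append(edge_lengths(g))
    return np.concatenate(pools)


def stage1_fit_beta(
    coords: CoordinateSet,
    reference_lengths: np.ndarray,
    alpha: float,
    beta_grid: Sequence[float] = BETA_GRID_DEFAULT,
    n_reps: int = 3,
    seed: int = 0,
    mean_degree: float = 12.0,
    l0: float = 15.0,
) -> tuple[float, np.ndarray]:
    """beta minimizing EMD(model edge lengths, reference) at fixed alpha.

    Returns (beta_opt, curve) where ``curve[k]`` is the EMD at
    ``beta_grid[k]``, each an average over ``n_reps`` pooled model draws.
    """
    reference_lengths = np.asarray(reference_lengths, dtype=float)
    if reference_lengths.size == 0:
        raise ValueError("reference_lengths must be nonempty")
    curve = np.empty(len(beta_grid))
    for k, beta in enumerate(beta_grid):
        pooled = _pooled_lengths(
            coords, alpha, float(beta), n_reps, seed + 1000 * k, mean_degree, l0
        )
        curve[k] = emd_1d(pooled, reference_lengths)
    return float(beta_grid[int(np.argmin(curve))]), curve


def _pooled_spectrum(
    coords: CoordinateSet,
    alpha: float,
    beta: float,
    k_eigs,
    n_reps: int,
    seed: int,
    mean_degree: float,
    l0: float,
) -> np.ndarray:
    pools = []
    for rep in range(n_reps):
        cfg = _model_config(coords, alpha, beta, mean_degree, l0, seed + rep)
        g = generate_model(coords, cfg)
        vals = eigh(build_matrix(g, "normalized_laplacian"), eigvals_only=True)
        if k_eigs not in (None, "all"):
            vals = np.sort(vals)[: int(k_eigs)]
        pools.append(vals)
    return np.concatenate(pools)


def stage2_fit_alpha(
    coords: CoordinateSet,
    reference_spectrum: np.ndarray,
    beta_opt_map: Mapping[float, float],
    alpha_grid: Sequence[float] = ALPHA_GRID_DEFAULT,
    k_eigs="all",
    n_reps: int = 3,
    seed: int = 0,
    mean_degree: float = 12.0,
    l0: float = 15.0,
) -> tuple[float, np.ndarray]:
    """alpha minimizing EMD between normalized-Laplacian spectra.

    For each alpha, models M(alpha, beta_opt(alpha)) are generated and their
    first ``k_eigs`` eigenvalues pooled; the EMD to ``reference_spectrum`` is
    the stage-2 objective.  ``beta_opt_map`` must cover ``alpha_grid``.
    """
    missing = [a for a in alpha_grid if float(a) not in beta_opt_map]
    if missing:
        raise ValueError(f"beta_opt_map missing alphas {missing}")
    ref = np.asarray(reference_spectrum, dtype=float)
    if k_eigs not in (None, "all"):
        ref = np.sort(ref)[: int(k_eigs)]
    curve = np.empty(len(alpha_grid))
    for k, alpha in enumerate(alpha_grid):
        pooled = _pooled_spectrum(
            coords,
            float(alpha),
            beta_opt_map[float(alpha)],
            k_eigs,
            n_reps,
            seed + 10_000 * k,
            mean_degree,
            l0,
        )
        curve[k] = emd_1d(pooled, ref)
    return float(alpha_grid[int(np.argmin(curve))]), curve


@dataclass
class FitResult:
    """Full two-stage fit: per-alpha stage-1 curves and the stage-2 curve."""

    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    beta_opt: dict[float, float]
    stage1_curves: dict[float, np.ndarray]
    stage2_curve: np.ndarray
    alpha_opt: float
    n_reps: int
    seed: int

    @property
    def beta_opt_at_alpha_opt(self) -> float:
        return self.beta_opt[self.alpha_opt]


def fit_ngpa(
    coords: CoordinateSet,
    reference_lengths: np.ndarray,
    reference_spectrum: np.ndarray,
    alpha_grid: Sequence[float] = ALPHA_GRID_DEFAULT,
    beta_grid: Sequence[float] = BETA_GRID_DEFAULT,
    k_eigs="all",
    n_reps: int = 3,
    seed: int = 0,
    mean_degree: float = 12.0,
    l0: float = 15.0,
) -> FitResult:
    """Run the complete two-stage parameter search."""
    beta_opt: dict[float, float] = {}
    stage1_curves: dict[float, np.ndarray] = {}
    for i, alpha in enumerate(alpha_grid):
        b, curve = stage1_fit_beta(
            coords,
            reference_lengths,
            float(alpha),
            beta_grid=beta_grid,
            n_reps=n_reps,
            seed=seed + 100_000 * i,
            mean_degree=mean_degree,
            l0=l0,
        )
        beta_opt[float(alpha)] = b
        stage1_curves[float(alpha)] = curve
    alpha_opt, stage2_curve = stage2_fit_alpha(
        coords,
        reference_spectrum,
        beta_opt,
        alpha_grid=alpha_grid,
        k_eigs=k_eigs,
        n_reps=n_reps,
        seed=seed + 777,
        mean_degree=mean_degree,
        l0=l0,
    )
    return FitResult(
        alpha_grid=np.asarray(alpha_grid, dtype=float),
        beta_grid=np.asarray(beta_grid, dtype=float),
        beta_opt=beta_opt,
        stage1_curves=stage1_curves,
        stage2_curve=stage2_curve,
        alpha_opt=alpha_opt,
        n_reps=n_reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# interhemispheric cut experiment
# ---------------------------------------------------------------------------

def remove_interhemispheric(
    g: SpatialGraph, fraction: float, seed: int = 0
) -> SpatialGraph:
    """Remove round(fraction * E_interhem) random interhemispheric edges.

    Intrahemispheric edges are never touched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    inter = sorted(g.interhemispheric_edges())
    n_cut = int(round(fraction * len(inter)))
    rng = np.random.default_rng(seed)
    cut = set(map(tuple, rng.permutation(inter)[:n_cut].tolist())) if n_cut else set()
    cut = {(int(u), int(v)) for u, v in cut}
    out = g.copy()
    out.edges = {e for e in g.edges if e not in cut}
    return out


def _low_norm_laplacian_eigs(g: SpatialGraph, k: int = 4) -> np.ndarray:
    """Lowest k normalized-Laplacian eigenvalues; union spectrum across
    components.  Nodes isolated by edge removal contribute eigenvalue 0."""
    a = g.adjacency()
    deg = a.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = np.diag(deg) - a
    lnorm = lap * inv_sqrt[:, None] * inv_sqrt[None, :]
    vals = eigh(lnorm, eigvals_only=True, subset_by_index=[0, min(k, len(deg)) - 1])
    return np.sort(vals)


@dataclass
class CutTrajectory:
    """Low-mode trajectories under progressive interhemispheric edge removal."""

    fractions: np.ndarray
    lambda2: np.ndarray  # (n_fractions,) ensemble means
    lambda3: np.ndarray
    lambda4: np.ndarray
    lambda2_sd: np.ndarray
    lambda3_sd: np.ndarray
    lambda4_sd: np.ndarray
    relative_delta3: float
    relative_delta4: float


def cut_experiment(
    g: SpatialGraph,
    fractions: Sequence[float] = tuple(np.linspace(0, 1, 11)),
    n_reps: int = 20,
    seed: int = 0,
) -> CutTrajectory:
    """Track (lambda_2, lambda_3, lambda_4) while cutting interhemispheric edges.

    For each removal fraction, ``n_reps`` independent uniform edge subsets are
    removed and the three lowest nontrivial normalized-Laplacian eigenvalues
    recorded (at full cut the union spectrum of the two components is used, so
    lambda_2 = 0 appears).  Relative deltas are
    (lambda_full_cut - lambda_intact) / lambda_intact, signed.
    """
    if not g.interhemispheric_edges():
        raise ValueError("graph has no interhemispheric edges to cut")
    fractions = np.asarray(fractions, dtype=float)
    per_frac = np.empty((len(fractions), n_reps, 3))
    for i, frac in enumerate(fractions):
        for rep in range(n_reps):
            cut = remove_interhemispheric(g, float(frac), seed=seed + 97 * i + rep)
            vals = _low_norm_laplacian_eigs(cut, k=4)
            per_frac[i, rep] = vals[1:4]
    means = per_frac.mean(axis=1)
    sds = per_frac.std(axis=1, ddof=1) if n_reps > 1 else np.zeros_like(means)
    intact = _low_norm_laplacian_eigs(g, k=4)
    full = remove_interhemispheric(g, 1.0, seed=seed)
    full_vals = _low_norm_laplacian_eigs(full, k=4)
    rel3 = float((full_vals[2] - intact[2]) / intact[2])
    rel4 = float((full_vals[3] - intact[3]) / intact[3])
    return CutTrajectory(
        fractions=fractions,
        lambda2=means[:, 0],
        lambda3=means[:, 1],
        lambda4=means[:, 2],
        lambda2_sd=sds[:, 0],
        lambda3_sd=sds[:, 1],
        lambda4_sd=sds[:, 2],
        relative_delta3=rel3,
        relative_delta4=rel4,
    )
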