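"""Cross-scale eigenmode matching and multifractal dimension estimation.

A single physical eigenmode observed at several network resolutions N lets
one estimate its fractal dimension: IPR_q ~ N^{-tau_q} with tau_q =
D_q (q - 1), D_q = 0 for localized and D_q = 1 for fully extended modes.
Weak multifractality shows up as a small quadratic correction,
tau_q = d (q - 1) + gamma q (1 - q) with |gamma| << 1.

Modes are matched across scales by projecting each eigenvector onto a common
ROI label space (summed squared amplitudes per region), requiring small
Jensen-Shannon divergence between the projections at every pair of scales and
a stable relative spectral position mu_i = i / N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .localization import ipr
from .spectral import EigenSystem

__all__ = [
    "ModeGroup",
    "TauFit",
    "roi_projection",
    "jsd",
    "match_modes_across_scales",
    "fit_tau",
    "weak_multifractality_fit",
    "DEFAULT_Q_GRID",
]

#: q = 1 excluded (D_q singular there)
DEFAULT_Q_GRID = (0.5, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


def roi_projection(
    psi: np.ndarray, roi_labels: np.ndarray, n_roi: Optional[int] = None
) -> np.ndarray:
    """Project a unit eigenvector onto the ROI label space.

    a_i = sum_{k in ROI_i} psi(k)^2 — the probability mass the mode places on
    each region; sums to 1.
    """
    psi = np.asarray(psi, dtype=float)
    labels = np.asarray(roi_labels, dtype=int)
    if labels.shape != psi.shape:
        raise ValueError("roi labels must cover every eigenvector component")
    if labels.min() < 0:
        raise ValueError("roi labels must be nonnegative")
    k = n_roi if n_roi is not None else int(labels.max()) + 1
    if labels.max() >= k:
        raise ValueError("roi label outside [0, n_roi)")
    weights = psi**2
    weights = weights / weights.sum()
    return np.bincount(labels, weights=weights, minlength=k)


def jsd(p: np.ndarray, r: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits (base-2 log), range [0, 1].

    0 for identical distributions, 1 for disjoint supports; 0 log 0 := 0.
    """
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if p.shape != r.shape:
        raise ValueError("distributions must have equal length")
    if np.any(p < 0) or np.any(r < 0):
        raise ValueError("distributions must be nonnegative")
    for v in (p, r):
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("distributions must sum to 1")
    # scipy returns the square root of the divergence
    return float(jensenshannon(p, r, base=2) ** 2)


@dataclass
class ModeGroup:
    """One eigenmode tracked across resolutions.

    ``entries`` holds per-scale (scale_id, mode index, mu = i/N, eigenvector);
    ``pairwise_jsd`` the ROI-projection divergences over all scale pairs.
    """

    entries: list[tuple[int, int, float, np.ndarray]]
    pairwise_jsd: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def scales(self) -> list[int]:
        return [e[0] for e in self.entries]

    @property
    def max_jsd(self) -> float:
        return max(self.pairwise_jsd.values()) if self.pairwise_jsd else 0.0


def _projections(es: EigenSystem, labels: np.ndarray, n_roi: int) -> np.ndarray:
    return np.stack(
        [roi_projection(es.eigenvectors[:, i], labels, n_roi) for i in range(es.n)]
    )


def match_modes_across_scales(
    eigensystems: Sequence[EigenSystem],
    roi_labels: Sequence[np.ndarray],
    jsd_max: float = 0.4,
    mu_tol: float = 0.05,
) -> list[ModeGroup]:
    """Greedy coarse-to-fine eigenmode matching across resolutions.

    Scales must be ordered coarse to fine and share one ROI label space.  Each
    coarsest-scale mode seeds a chain; at every finer scale the unclaimed
    candidate minimizing the ROI-projection JSD among those with
    |mu^S - mu^{S+1}| < ``mu_tol`` is appended (ties by smaller |delta mu|).
    A completed chain is accepted only if every one of its C(S, 2) pairwise
    JSD values is <= ``jsd_max``; each mode joins at most one group.
    """
    n_scales = len(eigensystems)
    if n_scales < 2:
        raise ValueError("need at least 2 scales")
    if len(roi_labels) != n_scales:
        raise ValueError("one ROI label array per scale required")
    n_roi = int(max(np.max(l) for l in roi_labels)) + 1
    projs = [
        _projections(es, np.asarray(lab), n_roi)
        for es, lab in zip(eigensystems, roi_labels)
    ]
    mus = [np.arange(1, es.n + 1) / es.n for es in eigensystems]
    claimed: list[set[int]] = [set() for _ in range(n_scales)]
    groups: list[ModeGroup] = []
    for i0 in range(eigensystems[0].n):
        chain = [(0, i0)]
        ok = True
        for s in range(1, n_scales):
            prev_s, prev_i = chain[-1]
            mu_prev = mus[prev_s][prev_i]
            cands = [
                j
                for j in range(eigensystems[s].n)
                if j not in claimed[s] and abs(mus[s][j] - mu_prev) < mu_tol
            ]
            if not cands:
                ok = False
                break
            p_prev = projs[prev_s][prev_i]
            scored = sorted(
                cands,
                key=lambda j: (
                    round(jsd(p_prev, projs[s][j]), 12),
                    abs(mus[s][j] - mu_prev),
                    j,
                ),
            )
            chain.append((s, scored[0]))
        if not ok:
            continue
        pairwise = {
            (sa, sb): jsd(projs[sa][ia], projs[sb][ib])
            for (sa, ia), (sb, ib) in combinations(chain, 2)
        }
        if any(v > jsd_max for v in pairwise.values()):
            continue
        entries = [
            (s, i, float(mus[s][i]), eigensystems[s].eigenvectors[:, i])
            for s, i in chain
        ]
        groups.append(ModeGroup(entries=entries, pairwise_jsd=pairwise))
        for s, i in chain:
            claimed[s].add(i)
    return groups


@dataclass
class TauFit:
    """Per-q IPR scaling exponents and derived fractal dimensions."""

    q_grid: np.ndarray
    tau: np.ndarray
    r2: np.ndarray
    d_q: np.ndarray
    accepted: bool
    d: Optional[float] = None
    gamma: Optional[float] = None
    gamma_se: Optional[float] = None

    @property
    def is_multifractal(self) -> Optional[bool]:
        """True when the quadratic term is resolved (|gamma| > 2 SE)."""
        if self.gamma is None or self.gamma_se is None:
            return None
        if self.gamma_se == 0:
            return bool(abs(self.gamma) > 0)
        return bool(abs(self.gamma) > 2 * self.gamma_se)


def fit_tau(
    sizes: Sequence[int],
    ipr_by_q: np.ndarray,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    r2_min: float = 0.95,
) -> TauFit:
    """Estimate tau_q from IPR_q across system sizes.

    ``ipr_by_q[k, s]`` is IPR at q_grid[k] for size sizes[s].  Per q, the
    least-squares slope of log IPR_q vs log N is -tau_q; D_q = tau_q/(q - 1).
    The fit is accepted only if R^2 > ``r2_min`` for every q and every D_q
    stays inside the physical band [0, 1] up to numerical slack of 0.05
    (dimensions outside it indicate a mis-matched mode chain, not fractality).
    """
    sizes = np.asarray(sizes, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 scales")
    if np.any(np.isclose(q_grid, 1.0)):
        raise ValueError("q = 1 excluded (D_q singular)")
    vals = np.asarray(ipr_by_q, dtype=float)
    logn = np.log(sizes)
    tau = np.empty(q_grid.size)
    r2 = np.empty(q_grid.size)
    for k in range(q_grid.size):
        y = np.log(vals[k])
        slope, intercept = np.polyfit(logn, y, 1)
        pred = slope * logn + intercept
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2[k] = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
        tau[k] = -slope
    d_q = tau / (q_grid - 1.0)
    accepted = bool(
        np.all(r2 > r2_min) and np.all(d_q > -0.05) and np.all(d_q < 1.05)
    )
    fit = TauFit(q_grid=q_grid, tau=tau, r2=r2, d_q=d_q, accepted=accepted)
    if q_grid.size >= 4:
        d, gamma, se = weak_multifractality_fit(fit)
        fit.d, fit.gamma, fit.gamma_se = d, gamma, se
    return fit


def ipr_table_for_group(
    group: ModeGroup, q_grid: Sequence[float] = DEFAULT_Q_GRID
) -> tuple[np.ndarray, np.ndarray]:
    """Sizes and IPR_q matrix (n_q, n_scales) for a matched mode group."""
    sizes = np.array([len(vec) for _, _, _, vec in group.entries], dtype=float)
    table = np.array(
        [[ipr(vec, q) for _, _, _, vec in group.entries] for q in q_grid]
    )
    return sizes, table


def weak_multifractality_fit(tf: TauFit) -> tuple[float, float, float]:
    """Least-squares (d, gamma) in tau_q = d (q - 1) + gamma q (1 - q).

    Returns (d, gamma, standard error of gamma); |gamma| > 2 SE is the
    multifractality verdict.
    """
    q = np.asarray(tf.q_grid, dtype=float)
    if np.unique(q).size < 2:
        raise ValueError("need at least 2 distinct q values")
    if q.size < 4:
        raise ValueError("need at least 4 q values")
    x = np.stack([q - 1.0, q * (1.0 - q)], axis=1)
    coef, residuals, rank, _ = np.linalg.lstsq(x, tf.tau, rcond=None)
    d, gamma = float(coef[0]), float(coef[1])
    dof = q.size - 2
    resid = tf.tau - x @ coef
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return d, gamma, float(np.sqrt(cov[1, 1]))
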