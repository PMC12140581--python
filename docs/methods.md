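# Methods

## Model

The generator grows a simple undirected graph over a fixed set of 3-D node
positions split into left/right hemispheres.  Nodes are visited once each in
a random order; the visit of node *i* draws `m_i ~ U{1, …, round(2E_h/N_h)}`
and attaches *i* to `m_i` distinct targets with probability

    p_ij ∝ (d_j + 1)^α · exp(−β r_ij / l0),

`d_j` being the target's degree in the partially built graph, `r_ij` the
Euclidean distance (mm) and `l0` a fixed length unit.  The `+1` gives
isolated nodes nonzero attachment probability; `α = 1` is classical linear
preferential attachment, `α > 2` the winner-takes-all regime; `β` sets the
geometric cutoff `r0 = l0/β` beyond which links are exponentially rare.
Growth is run independently per hemisphere and `E_interhem` uniformly chosen
cross-hemisphere pairs are added afterwards, reflecting the view that
interhemispheric fibres are not part of the same stochastic growth process.

Assumptions: binary undirected edges (no weights, no directions), Euclidean
distance as a proxy for fibre length, hemispheres grown from identical rules,
interhemispheric wiring uniform.

### Conventions resolved during implementation

* **Degree snapshot.** All `m_i` draws of one visit use the degrees as they
  were when the visit began; degrees update once the visit completes.  This
  makes a visit's draws exchangeable and the result insensitive to the
  within-visit draw order.
* **Global simplicity.** The candidate set excludes the visited node and
  *all* of its current neighbours, including links acquired during earlier
  visits, so double connections can never arise.
* **Edge budget per hemisphere.** The `2E/N` bound on `m_i` uses the
  hemisphere's own `E_h` and `N_h`, since growth is per hemisphere.  The
  realised edge count exceeds the nominal target by up to ~10–15% (each node
  initiates `(1+m)/2` links on average and also receives links); the density
  invariant is checked at the 15% level.
* **Sampling without replacement.** Targets are drawn sequentially with
  renormalization, implemented by the equivalent Gumbel-top-k construction
  on the log-weights.  Working in the log domain matters: at large `β` the
  raw weights underflow and a naive implementation would fall back to
  uniform choices, destroying the nearest-neighbour limit `M(0, β→∞)`.
* **Connectivity repair.** The analyses assume a connected graph.  Policy
  `nearest_attach` (default) links each stray component to its geometrically
  nearest giant-component node and reports the added edges separately in the
  graph metadata; `regenerate` redraws with an incremented seed.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α | 3.0 | – | fitted optimum for human connectomes |
| β | 4.5 | – | fitted optimum; gives `r0 = l0/β ≈ 3.3 mm` |
| l0 | 15 | mm | mean intrahemispheric link length of reference connectomes |
| mean degree 2E/N | 12 | – | plausible density for 1000-node parcellations; the reference datasets do not print it, so it is a package assumption |
| E_interhem | 2% of E | – | interhemispheric fibres are few relative to E |
| hemisphere boxes | 65 × 140 × 110 | mm | human-hemisphere extents; 4 mm midline gap |

## Synthetic pseudoconnectomes

`generate_pseudoconnectome` places ⌈n/2⌉ / ⌊n/2⌋ nodes uniformly inside the
two boxes.  ROI partitions come from seeded k-means per hemisphere (labels
never straddle the midline); nested multiscale families are built by
clustering the finest scale and keeping the member nearest each cluster
centre, so coarser scales are true subsets and inherit the finest-scale ROI
labels.

What this emulates about real data: uniform spatial support per hemisphere,
spatially coherent parcels, balanced hemispheres, and nesting across
resolutions.  What it does not: anatomical parcel shapes and sizes, cortical
folding and surface geometry, the hub placement of real anatomy, and any
subject-level variability.  Tests passing on pseudoconnectomes therefore
validate the algorithms and the geometry-driven spectral phenomenology
(cluster modes, scar bands, density shapes); they do not certify agreement
with any particular empirical connectome.

## Spectral analysis choices

* Full dense symmetric eigensolves (`scipy.linalg.eigh`); the sizes used
  here (N ≤ ~2000) make iterative solvers unnecessary.
* **Soft modes** are normalized-Laplacian eigenvalues below 0.15, counting
  from `λ₂`: the trivial `λ₁ = 0` of a connected graph is excluded, so the
  count reads "number of weakly coupled clusters beyond overall
  connectivity".  Note `λ₂` itself reflects the hemisphere bipartition and
  is present in any two-hemisphere graph.
* **Spectral density** uses 100 uniform bins on [0, 2] for the normalized
  Laplacian so that networks of different size are binned identically.
* **EMD** (`emd_1d`) is the exact 1-D Wasserstein-1 distance on raw samples
  (area between empirical CDFs), not on binned densities, avoiding bin-width
  artefacts.
* **Return probability** `R(t) = (1/N) Σ exp(−t λ_i)` uses the unnormalized
  Laplacian.  The exponent fit scans all contiguous windows of the
  log-spaced grid spanning ≥ 1 decade, fits `log R` vs `log t` by least
  squares and keeps the window with maximal R²; windows with R² < 0.9 or
  |slope| < 0.05 (flat curve) are rejected, yielding an explicit
  "no power law" result instead of an exception.  Because `R(t)` saturates
  at exactly `(number of components)/N`, a power law cannot hold near the
  plateau; when the asymptote is known the optional `asymptote` argument
  subtracts it before fitting so the saturation shoulder is not mistaken
  for a scaling window.  The acceptance pipeline uses `asymptote = 1/N`.

## Localization and TENs

* `IPR_q = Σ_n |ψ(n)|^{2q}` on unit eigenvectors; bounds `N^{1−q} ≤ IPR_q ≤ 1`
  for `q > 1`.
* TEN candidacy compares neighbour sets with the pair itself removed
  (`exclude_pair`), otherwise the mutual edge of a connected pair would cap
  the Jaccard index below 1 and "ideal connected TEN" would be unattainable;
  this convention is exactly what makes the connected ideal pair an
  eigenvector of the adjacency matrix with eigenvalue −1.
* Candidate pairs are restricted to graph distance ≤ 2 (adjacent or sharing
  a neighbour) — exact for any positive threshold, since farther pairs have
  Jaccard 0 — which keeps 1000-node scans fast.  A brute-force all-pairs
  oracle checks the pruning on small graphs.
* Inside a degenerate eigenspace the IPR is basis-dependent.  The solver's
  basis is reported as-is; for TEN association, difference vectors
  `e_u − e_v` are projected onto each degenerate block and accepted when the
  block carries their full norm (`pair_difference_eigenvalue`,
  `minimal_support_rotation`).

## Multifractal analysis

* ROI projection: `a_k = Σ_{n∈ROI_k} ψ(n)²` — the probability mass per
  region; JSD between projections uses base-2 logarithms so the 0.4
  acceptance threshold lives on the [0, 1] scale.
* Matching is greedy coarse-to-fine: each coarsest mode seeds a chain; at
  the next scale the unclaimed candidate with minimal JSD among those with
  `|Δμ| < 0.05` (μ = i/N, the relative spectral position) is appended, ties
  broken by smaller `|Δμ|` then lower index; the completed chain must pass
  `JSD ≤ 0.4` for **every** pair of scales.  Greediness is a pragmatic
  choice — the criteria define validity, not an assignment algorithm — and
  claimed-mode bookkeeping keeps groups disjoint.
* `fit_tau` needs ≥ 3 scales and excludes `q = 1` (`D_q` singular).  The
  default grid is q ∈ {0.5, 1.5, 2, 2.5, 3, 3.5, 4}.  Fits are accepted only
  when R² > 0.95 at every q **and** every `D_q` lies in [−0.05, 1.05]:
  dimensions outside the physical band signal a mis-matched mode chain
  rather than genuine fractality.  Families built from 125-node bases follow
  the practice of excluding scales below ~100 nodes, where single-mode IPRs
  are too coarse.
* Weak multifractality: ordinary least squares of `τ_q` on the basis
  `{(q−1), q(1−q)}`; the mode is called multifractal when `|γ|` exceeds
  twice its standard error.

## Graph metrics

* Topological overlap `O_ij = (C(i,j) + A_ij)/(min(k_i,k_j) + 1 − A_ij)`
  with `O_ii = 1`; local clustering via networkx.
* Rich club `φ(k) = 2E_{>k}/(N_{>k}(N_{>k}−1))` on the subgraph of nodes
  with degree strictly above k; levels with fewer than 2 surviving nodes are
  omitted (raw curve, no degree-preserving normalisation).
* Hyperbolicity uses the four-point condition with `δ = M₁ − M₂` — the
  difference of the two largest pairwise-sum values, **not** the halved
  variant — averaged over 4-subsets.  Exact enumeration is used up to 10⁶
  subsets; beyond that an unbiased uniform sample (default 10⁵) with a
  reported standard error.  All-pairs distances come from unweighted BFS.

## Parameter fitting and the cut experiment

Fitting is two-stage to keep the search one-dimensional per α and to
guarantee the selected model is geometrically consistent before spectra are
compared: stage 1 minimises the EMD between pooled intrahemispheric
edge-length distributions over β (full grid [0, 8] step 0.1), stage 2
minimises the EMD between pooled normalized-Laplacian spectra over α (full
grid [0, 5] step 0.5) at `β_opt(α)`.  Defaults pool 3 model draws per grid
point; the self-recovery checks use 5.  The test and example profiles run
N = 400–500 nodes with grids reduced to a window around the reference
optimum (same grid steps) — problem sizes chosen to make the demonstrations
quick while preserving one-grid-step resolution, which is also the intrinsic
resolution of the objective: models with compensated `(α, β_opt(α))` pairs
are spectrally very close, so recovery to within one grid step in each
parameter is the expected outcome, not a weakness of the optimiser.

The cut experiment removes `round(f · E_interhem)` uniformly chosen
interhemispheric edges per fraction f — an independent subset per fraction
and repetition — and records `λ₂, λ₃, λ₄` of the normalized Laplacian.  At
full cut the spectrum is the union over the two components, so `λ₂ = 0`
appears; nodes isolated by the cut contribute eigenvalue 0 by the
`d^{-1/2} := 0` convention.  Relative changes are signed:
`(λ_full − λ_intact)/λ_intact`.

## Reproducibility

Every stochastic stage derives its seed from a global seed and a stage label
via BLAKE2b (`derive_seed`), truncated to 31 bits; CLI runs write a JSON
manifest (parameters, seeds, version) sufficient for bit-exact re-runs.

## Known limitations

* Weighted and directed networks are out of scope; all inputs are binarised.
* The pseudoconnectome geometry is a box model; results depending on
  cortical surface geometry cannot be studied with it.
* The rich-club organisation of real connectomes is not reproduced by the
  growth rule (no core-forcing mechanism), and the connected-TEN band at
  adjacency eigenvalue −1 is suppressed at strong geometric penalties, where
  the cutoff scale falls below the typical distance between interacting
  TENs.
* Mean-degree and interhemispheric-count defaults are assumptions, not
  fitted values; analyses sensitive to absolute density should set them
  explicitly.
* The return-probability exponent is an adaptive-window estimate; on curves
  without an extended scaling regime the chosen window, and hence the
  exponent, can be sensitive to the window-selection rule, which is why the
  fit reports the window and R² alongside ξ and supports asymptote removal.
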