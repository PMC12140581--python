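"""Normalized-Laplacian spectral density: geometry-aware vs random model.

The geometry-aware model develops isolated low-lying "soft" cluster modes
(lambda < 0.15) and a sharp heterogeneity peak near lambda = 1; the blind
random model M(0,0) shows only the ever-present hemisphere mode lambda_2 and
a smooth semicircle-like bulk.
"""

import numpy as np

import ngpa
from ngpa import (
    count_soft_modes,
    default_config,
    generate_model,
    generate_pseudoconnectome,
    graph_eigensystem,
    spectral_density,
)

edges = np.linspace(0, 2, 101)
centers = 0.5 * (edges[:-1] + edges[1:])

for label, alpha, beta in [("NGPA M(3, 4.5)", 3.0, 4.5), ("random M(0, 0)", 0.0, 0.0)]:
    soft, dens = [], []
    for s in range(5):
        cs = generate_pseudoconnectome(500, seed=10 + s)
        g = generate_model(cs, default_config(500, alpha=alpha, beta=beta, seed=s))
        es = graph_eigensystem(g, "normalized_laplacian")
        soft.append(count_soft_modes(es))
        dens.append(spectral_density(np.clip(es.eigenvalues, 0, 2), edges))
    mean_d = np.mean(dens, axis=0)
    print(f"{label}:")
    print(f"  soft cluster modes (lambda < 0.15, lambda_1 excluded): "
          f"{np.mean(soft):.1f} +/- {np.std(soft):.1f}")
    print(f"  bulk peak at lambda = {centers[np.argmax(mean_d)]:.2f}, "
          f"height {mean_d.max():.2f}")
print("soft modes count weakly coupled spatial clusters; only the")
print("geometry-aware model produces them beyond the hemisphere mode")
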