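"""Topological overlap, clustering, rich club and Gromov hyperbolicity.

These are the topology-side fingerprints used to compare generative models:
overlap and clustering capture local redundancy, the rich-club curve the
core density, and four-point hyperbolicity the tree-likeness of shortest
paths (smaller delta = more hyperbolic).
"""

import numpy as np

from ngpa import (
    default_config,
    generate_model,
    generate_pseudoconnectome,
    hyperbolicity,
    local_clustering,
    rich_club,
    topological_overlap,
)

cs = generate_pseudoconnectome(300, seed=6)
for label, alpha, beta in [("NGPA M(3,4.5)", 3.0, 4.5), ("w/o geometry M(3,0)", 3.0, 0.0)]:
    g = generate_model(cs, default_config(300, alpha=alpha, beta=beta, seed=6))
    o = topological_overlap(g)
    iu = np.triu_indices_from(o, k=1)
    cc = local_clustering(g)
    rc = rich_club(g)
    hyp = hyperbolicity(g, mode="sampled", n_samples=50_000, seed=0)
    print(f"{label}:")
    print(f"  mean topological overlap: {o[iu].mean():.3f}")
    print(f"  mean local clustering:    {cc.mean():.3f}")
    print(f"  rich-club phi at k=20:    {rc.get(20, float('nan')):.3f}")
    print(f"  hyperbolicity delta(G):   {hyp.delta:.3f} "
          f"+/- {hyp.std_error:.3f} ({hyp.n_samples} sampled 4-sets)")
print("the geometric penalty boosts local overlap/clustering; removing it")
print("concentrates shortest paths on superhubs, lowering delta")
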