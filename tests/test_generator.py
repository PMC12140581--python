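import numpy as np
import pytest
from scipy.stats import chisquare

from ngpa import (
    NGPAConfig,
    attachment_weights,
    default_config,
    generate_model,
    generate_pseudoconnectome,
    grow_hemisphere,
)


def cfg(alpha=0.0, beta=0.0, l0=15.0, **kw):
    kw.setdefault("e_interhem", 1)
    return NGPAConfig(alpha=alpha, beta=beta, l0=l0, **kw)


class TestAttachmentWeights:
    def test_linear_pa_no_geometry(self):
        p = attachment_weights([1, 3], [1.0, 1.0], cfg(alpha=1.0))
        assert p == pytest.approx([1 / 3, 2 / 3])

    def test_pure_geometry(self):
        # degrees equal; distances l0 and 2 l0 at beta=1 -> 1/(1+e^-1), ...
        p = attachment_weights([0, 0], [15.0, 30.0], cfg(beta=1.0))
        assert p == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_uniform_when_blind(self):
        p = attachment_weights([0, 0, 0, 0], [1, 2, 3, 4], cfg())
        assert p == pytest.approx([0.25] * 4)

    def test_normalized_and_scale_invariant(self):
        c = cfg(alpha=2.0, beta=1.5)
        p = attachment_weights([0, 1, 2, 5], [1, 5, 10, 2], c)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()

    def test_monotone_in_degree_and_distance(self):
        c = cfg(alpha=1.5, beta=2.0)
        base = attachment_weights([2, 2, 2], [10, 10, 10], c)
        bumped = attachment_weights([4, 2, 2], [10, 10, 10], c)
        assert bumped[0] > base[0]
        pushed = attachment_weights([2, 2, 2], [20, 10, 10], c)
        assert pushed[0] < base[0]

    def test_extreme_penalty_degenerates_to_nearest(self):
        # log-domain stabilization: huge distances must not underflow the
        # whole distribution — the nearest candidate takes all the mass
        p = attachment_weights([0, 0], [1e9, 2e9], cfg(beta=8.0))
        assert p == pytest.approx([1.0, 0.0])

    def test_degenerate_weights_fall_back_to_uniform(self):
        p = attachment_weights([0, 0], [np.inf, np.inf], cfg(beta=1.0))
        assert p == pytest.approx([0.5, 0.5])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            attachment_weights([], [], cfg())


class TestGrowHemisphere:
    def test_two_nodes_single_edge(self, rng):
        edges = grow_hemisphere(np.zeros((2, 3)), cfg(), rng, target_edges=1)
        assert edges == {(0, 1)}

    def test_simple_graph_no_duplicates(self, rng):
        coords = rng.uniform(0, 50, size=(60, 3))
        edges = grow_hemisphere(coords, cfg(alpha=2, beta=3), rng, target_edges=180)
        assert all(u < v for u, v in edges)
        assert len(edges) == len(set(edges))

    def test_strong_geometry_links_near_neighbours(self):
        # beta -> large: each node's chosen targets are among its nearest
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 100, size=(40, 3))
        edges = grow_hemisphere(coords, cfg(beta=1e3), np.random.default_rng(5),
                                target_edges=80)
        from scipy.spatial.distance import cdist

        d = cdist(coords, coords)
        m_max = max(1, round(2 * 80 / 40))
        for u, v in edges:
            # v must be within u's (or u within v's) 2*m_max nearest nodes
            rank_uv = np.sum(d[u] < d[u, v])
            rank_vu = np.sum(d[v] < d[v, u])
            assert min(rank_uv, rank_vu) <= 2 * m_max

    def test_expected_edge_count(self):
        # visits draw m_i ~ U[1, m], so E[edges] ≈ N (1 + m)/2 less duplicates
        n, target = 200, 600
        m = round(2 * target / n)
        counts = [
            len(
                grow_hemisphere(
                    np.random.default_rng(s).uniform(0, 60, (n, 3)),
                    cfg(),
                    np.random.default_rng(s),
                    target_edges=target,
                )
            )
            for s in range(30)
        ]
        expected = n * (1 + m) / 2
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)


class TestGenerateModel:
    def test_connected_with_single_zero_mode(self, small_coords):
        from ngpa import count_soft_modes, graph_eigensystem

        g = generate_model(small_coords, default_config(small_coords.n_nodes, seed=3))
        es = graph_eigensystem(g, "laplacian")
        assert np.sum(np.abs(es.eigenvalues) < 1e-10) == 1

    def test_interhemispheric_budget_exact(self, small_coords):
        c = default_config(small_coords.n_nodes, seed=1)
        g = generate_model(small_coords, c)
        inter = g.interhemispheric_edges()
        repair = set(g.meta["repair_edges"])
        assert len(inter - repair) == c.e_interhem

    def test_deterministic_for_seed(self, small_coords):
        c = default_config(small_coords.n_nodes, seed=11)
        assert generate_model(small_coords, c).edges == generate_model(small_coords, c).edges

    def test_geometry_blind_when_beta_zero(self, small_coords):
        from dataclasses import replace

        from ngpa.synth import CoordinateSet

        c = default_config(small_coords.n_nodes, alpha=2.0, beta=0.0, seed=5)
        g1 = generate_model(small_coords, c)
        # rigid motion: translate + rotate 90 degrees about z
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        moved = CoordinateSet(
            coords=small_coords.coords @ rot.T + np.array([100.0, -30.0, 7.0]),
            hemisphere=small_coords.hemisphere,
        )
        g2 = generate_model(moved, c)
        assert g1.edges == g2.edges

    def test_density_close_to_target(self):
        # |E - E_target| / E_target stays under 15% across seeds
        cs = generate_pseudoconnectome(500, seed=0)
        ratios = []
        for s in range(10):
            c = default_config(500, seed=s)
            e_target = sum(c.target_edges_per_hemisphere.values()) + c.e_interhem
            g = generate_model(cs, c)
            ratios.append(abs(g.n_edges - e_target) / e_target)
        assert max(ratios) < 0.15

    def test_blind_model_is_homogeneous_pa_model_is_not(self):
        # M(0,0) is Erdős–Rényi-like: narrow, hub-free degree distribution.
        # The degrees are the sum of the node's own uniform draws and a
        # binomial count of incoming links, so the distribution is mildly
        # overdispersed relative to a pure binomial but stays homogeneous;
        # M(3, 0) ("winner takes all") grows superhubs instead.
        cs = generate_pseudoconnectome(1000, seed=2)
        deg_blind = generate_model(
            cs, default_config(1000, alpha=0, beta=0, seed=2)
        ).degrees()
        deg_pa = generate_model(
            cs, default_config(1000, alpha=3, beta=0, seed=2)
        ).degrees()
        # homogeneity: dispersion index near ER levels, no heavy tail
        assert deg_blind.var() / deg_blind.mean() < 3.0
        assert deg_blind.max() < deg_blind.mean() + 6 * deg_blind.std()
        # heterogeneity under preferential attachment dwarfs it
        assert deg_pa.max() > 3 * deg_blind.max()
        assert deg_pa.var() / deg_pa.mean() > 10 * deg_blind.var() / deg_blind.mean()

    def test_e_interhem_bound_checked(self, small_coords):
        with pytest.raises(ValueError):
            generate_model(
                small_coords,
                cfg(e_interhem=10**9, target_edges_per_hemisphere={"L": 30, "R": 30}),
            )
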