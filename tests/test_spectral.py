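import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngpa import (
    build_matrix,
    count_soft_modes,
    eigensystem,
    emd_1d,
    fit_return_exponent,
    graph_eigensystem,
    return_probability,
    spectral_density,
)

from .conftest import complete_graph, make_graph


class TestMatrices:
    def test_k2_laplacian(self):
        g = make_graph(2, [(0, 1)])
        assert build_matrix(g, "laplacian").tolist() == [[1, -1], [-1, 1]]

    def test_laplacian_rows_sum_to_zero(self):
        g = make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (1, 3)])
        assert build_matrix(g, "laplacian").sum(axis=1) == pytest.approx([0] * 5)

    def test_k2_normalized_laplacian_spectrum(self):
        es = graph_eigensystem(make_graph(2, [(0, 1)]), "normalized_laplacian")
        assert es.eigenvalues == pytest.approx([0.0, 2.0])

    def test_normalized_requires_positive_degrees(self):
        g = make_graph(3, [(0, 1)])
        with pytest.raises(ValueError):
            build_matrix(g, "normalized_laplacian")

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            build_matrix(make_graph(2, [(0, 1)]), "modularity")


class TestEigensystem:
    def test_k3_adjacency_spectrum(self):
        es = graph_eigensystem(complete_graph(3), "adjacency")
        assert es.eigenvalues == pytest.approx([-1, -1, 2])

    def test_adjacency_trace_zero(self):
        es = graph_eigensystem(complete_graph(5), "adjacency")
        assert es.eigenvalues.sum() == pytest.approx(0.0, abs=1e-10)

    def test_orthonormal_eigenvectors(self):
        es = graph_eigensystem(complete_graph(6), "laplacian")
        gram = es.eigenvectors.T @ es.eigenvectors
        assert np.abs(gram - np.eye(6)).max() < 1e-8

    def test_laplacian_eigen_sum_is_twice_edges(self):
        g = make_graph(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (0, 3)])
        es = graph_eigensystem(g, "laplacian")
        assert es.eigenvalues.sum() == pytest.approx(2 * g.n_edges)

    def test_normalized_bounds_and_bipartite_symmetry(self):
        # C6 is bipartite: spectrum symmetric about 1 and within [0, 2]
        from .conftest import cycle_graph

        es = graph_eigensystem(cycle_graph(6), "normalized_laplacian")
        lam = es.eigenvalues
        assert lam.min() > -1e-10 and lam.max() < 2 + 1e-10
        assert np.sort(lam) == pytest.approx(np.sort(2 - lam))

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            eigensystem(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestSpectralDensity:
    def test_single_value_single_bin(self):
        d = spectral_density([0.5], np.linspace(0, 1, 11))
        assert np.count_nonzero(d) == 1

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 2, 500)
        edges = np.linspace(0, 2, 101)
        d = spectral_density(vals, edges)
        assert np.sum(d * np.diff(edges)) == pytest.approx(1.0)

    def test_equally_spaced_is_flat(self):
        vals = np.arange(100) + 0.5
        edges = np.arange(0, 101, 10.0)
        d = spectral_density(vals, edges)
        assert np.allclose(d, d[0])

    def test_out_of_range_extends_with_warning(self):
        with pytest.warns(UserWarning):
            d = spectral_density([0.5, 3.0], np.linspace(0, 1, 5))
        assert d.size >= 4


class TestSoftModes:
    def test_counts_below_threshold_excluding_trivial(self):
        assert count_soft_modes(np.array([0.0, 0.02, 0.1, 0.2, 1.0])) == 2

    def test_complete_graph_has_none(self):
        es = graph_eigensystem(complete_graph(10), "normalized_laplacian")
        assert count_soft_modes(es) == 0

    def test_two_cliques_one_bridge_gives_one(self):
        cliques = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        edges = cliques + [(i + 10, j + 10) for i, j in cliques] + [(0, 10)]
        es = graph_eigensystem(make_graph(20, edges), "normalized_laplacian")
        assert count_soft_modes(es) == 1


class TestReturnProbability:
    def test_unity_at_zero(self):
        assert return_probability(np.array([0.0, 1.0, 5.0]), [0.0])[0] == 1.0

    def test_k2_value(self):
        r = return_probability(np.array([0.0, 2.0]), [1.0])
        assert r[0] == pytest.approx((1 + np.exp(-2)) / 2)

    def test_nonincreasing_and_limit(self):
        lam = np.array([0.0, 0.5, 1.2, 3.0])
        t = np.logspace(-2, 3, 50)
        r = return_probability(lam, t)
        assert (np.diff(r) <= 1e-15).all()
        assert r[-1] == pytest.approx(1 / 4)  # single zero mode -> 1/N

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            return_probability(np.array([0.0]), [-1.0])


class TestReturnExponentFit:
    t = np.logspace(-1, 3, 50)

    def test_exact_power_laws(self):
        for xi in (1.0, 0.5):
            fit = fit_return_exponent(self.t, self.t**-xi)
            assert fit.xi == pytest.approx(xi, abs=1e-10)
            assert fit.r2 == pytest.approx(1.0)

    def test_constant_is_not_a_power_law(self):
        fit = fit_return_exponent(self.t, np.full_like(self.t, 0.3))
        assert not fit.is_power_law

    def test_asymptote_subtraction_recovers_exponent(self):
        curve = self.t**-1.0 + 0.001
        raw = fit_return_exponent(self.t, curve)
        corrected = fit_return_exponent(self.t, curve, asymptote=0.001)
        assert corrected.xi == pytest.approx(1.0, abs=1e-10)
        assert abs(raw.xi - 1.0) > abs(corrected.xi - 1.0)

    def test_needs_two_decades(self):
        t = np.logspace(0, 1, 20)
        with pytest.raises(ValueError):
            fit_return_exponent(t, t**-1.0)


class TestEMD:
    def test_identity(self):
        x = [1.0, 2.0, 5.0]
        assert emd_1d(x, x) == 0.0

    def test_point_masses(self):
        assert emd_1d([0.0], [3.0]) == pytest.approx(3.0)

    def test_shifted_uniforms(self):
        assert emd_1d([0.0, 1.0], [1.0, 2.0]) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
    )
    def test_metric_axioms(self, a, b, c):
        dab, dba = emd_1d(a, b), emd_1d(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba)
        assert emd_1d(a, c) <= dab + emd_1d(b, c) + 1e-10
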