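import numpy as np
import pytest

from ngpa import (
    DEFAULT_Q_GRID,
    EigenSystem,
    fit_tau,
    jsd,
    match_modes_across_scales,
    roi_projection,
    weak_multifractality_fit,
)


class TestRoiProjection:
    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        psi = rng.normal(size=30)
        psi /= np.linalg.norm(psi)
        labels = rng.integers(0, 5, size=30)
        labels[:5] = np.arange(5)  # ensure all labels present
        a = roi_projection(psi, labels)
        assert a.sum() == pytest.approx(1.0)
        assert (a >= 0).all()

    def test_single_roi(self):
        psi = np.ones(4) / 2
        assert roi_projection(psi, np.zeros(4, dtype=int)).tolist() == [1.0]

    def test_delta_vector_is_indicator(self):
        psi = np.zeros(6)
        psi[4] = 1.0
        labels = np.array([0, 0, 1, 2, 3, 3])
        a = roi_projection(psi, labels)
        assert a.tolist() == [0, 0, 0, 1.0]

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            roi_projection(np.ones(3) / np.sqrt(3), np.array([0, 1]))


class TestJSD:
    def test_identity_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        assert jsd(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_reference_value(self):
        # JSD((1,0),(1/2,1/2)) = H(3/4,1/4) - 1/2 in bits
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)) - 0.5
        assert jsd(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(
            expected, abs=1e-4
        )
        assert expected == pytest.approx(0.3113, abs=1e-4)

    def test_symmetry_bounds_and_sqrt_triangle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p, q, r = (rng.dirichlet(np.ones(6)) for _ in range(3))
            assert jsd(p, q) == pytest.approx(jsd(q, p), abs=1e-12)
            assert 0 <= jsd(p, q) <= 1
            assert np.sqrt(jsd(p, r)) <= np.sqrt(jsd(p, q)) + np.sqrt(jsd(q, r)) + 1e-10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jsd(np.array([0.5, 0.6]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            jsd(np.array([1.5, -0.5]), np.array([0.5, 0.5]))


def _delta_system(roi_per_node):
    """Identity-basis system: mode i is a delta at node i, whose ROI
    projection is the indicator of roi_per_node[i]."""
    labels = np.asarray(roi_per_node, dtype=int)
    n = labels.size
    return (
        EigenSystem(
            kind="adjacency",
            eigenvalues=np.arange(n, dtype=float),
            eigenvectors=np.eye(n),
        ),
        labels,
    )


class TestModeMatching:
    def test_identical_scales_match_every_mode(self):
        systems, labels = zip(*[_delta_system([0, 1, 2, 3]) for _ in range(3)])
        groups = match_modes_across_scales(list(systems), list(labels))
        assert len(groups) == 4
        for g in groups:
            assert len(g.entries) == 3
            assert g.max_jsd == 0.0
            rois = {int(np.argmax(vec**2)) for _, _, _, vec in g.entries}
            assert len(rois) == 1  # matched mode stays on one node/ROI

    def test_mu_tolerance_blocks_displaced_partner(self):
        # every fine partner ROI sits at a relative position displaced by
        # more than mu_tol from its coarse counterpart
        coarse = _delta_system([0, 1, 2, 3])
        fine = _delta_system([0, 1, 2, 3, 4, 4, 4, 4])
        groups = match_modes_across_scales(
            [coarse[0], fine[0]], [coarse[1], fine[1]], mu_tol=0.05
        )
        assert groups == []

    def test_jsd_threshold_discards_mismatched_profiles(self):
        # mu-aligned candidates carry disjoint ROI indicators -> JSD = 1
        coarse = _delta_system([0, 1, 2, 3])
        fine = _delta_system([1, 0, 3, 2])
        groups = match_modes_across_scales(
            [coarse[0], fine[0]], [coarse[1], fine[1]], jsd_max=0.4, mu_tol=0.05
        )
        assert groups == []

    def test_each_fine_mode_claimed_once(self):
        # two coarse modes share one ROI: they may not share a fine partner
        coarse = _delta_system([0, 0])
        fine = _delta_system([0, 0])
        groups = match_modes_across_scales(
            [coarse[0], fine[0]], [coarse[1], fine[1]], mu_tol=1.0
        )
        fine_claims = [g.entries[1][1] for g in groups]
        assert len(fine_claims) == len(set(fine_claims))
        assert len(groups) == 2

    def test_requires_two_scales(self):
        sys0, lab0 = _delta_system([0, 1])
        with pytest.raises(ValueError):
            match_modes_across_scales([sys0], [lab0])


class TestFitTau:
    sizes = [125, 250, 500, 1000]

    def test_delocalized_limit(self):
        q = np.array(DEFAULT_Q_GRID)
        table = np.array([[n ** (1 - qq) for n in self.sizes] for qq in q])
        tf = fit_tau(self.sizes, table, q_grid=q)
        assert tf.tau == pytest.approx(q - 1, abs=1e-10)
        assert tf.d_q == pytest.approx(np.ones_like(q), abs=1e-10)
        assert tf.accepted

    def test_localized_limit(self):
        q = np.array(DEFAULT_Q_GRID)
        table = np.full((q.size, 4), 0.37)
        tf = fit_tau(self.sizes, table, q_grid=q)
        assert tf.tau == pytest.approx(np.zeros_like(q), abs=1e-12)
        assert tf.d_q == pytest.approx(np.zeros_like(q), abs=1e-12)

    def test_fractal_exponent_recovered(self):
        table = np.array([[n**-0.75 for n in self.sizes]])
        tf = fit_tau(self.sizes, table, q_grid=[2.0], r2_min=0.95)
        assert tf.tau[0] == pytest.approx(0.75, abs=1e-12)
        assert tf.d_q[0] == pytest.approx(0.75, abs=1e-12)
        assert tf.r2[0] == pytest.approx(1.0)

    def test_rejects_q_one_and_few_scales(self):
        with pytest.raises(ValueError):
            fit_tau(self.sizes, np.ones((1, 4)), q_grid=[1.0])
        with pytest.raises(ValueError):
            fit_tau([10, 20], np.ones((1, 2)), q_grid=[2.0])


class TestWeakMultifractality:
    q = np.array([0.5, 1.5, 2.0, 3.0, 4.0])

    def _tau_fit(self, tau):
        from ngpa import TauFit

        return TauFit(
            q_grid=self.q, tau=tau, r2=np.ones_like(self.q),
            d_q=tau / (self.q - 1), accepted=True,
        )

    def test_pure_fractal_gamma_zero(self):
        d, gamma, _ = weak_multifractality_fit(self._tau_fit(0.6 * (self.q - 1)))
        assert d == pytest.approx(0.6, abs=1e-12)
        assert gamma == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery(self):
        tau = 0.8 * (self.q - 1) + 0.05 * self.q * (1 - self.q)
        d, gamma, _ = weak_multifractality_fit(self._tau_fit(tau))
        assert d == pytest.approx(0.8, abs=1e-10)
        assert gamma == pytest.approx(0.05, abs=1e-10)

    def test_noisy_recovery_on_average(self):
        rng = np.random.default_rng(7)
        base = 0.8 * (self.q - 1) + 0.05 * self.q * (1 - self.q)
        ds = []
        for _ in range(100):
            d, _, _ = weak_multifractality_fit(
                self._tau_fit(base + rng.normal(0, 0.01, self.q.size))
            )
            ds.append(d)
        assert np.mean(ds) == pytest.approx(0.8, abs=0.02)

    def test_singular_design_rejected(self):
        from ngpa import TauFit

        tf = TauFit(
            q_grid=np.array([2.0, 2.0, 2.0]),
            tau=np.ones(3), r2=np.ones(3), d_q=np.ones(3), accepted=True,
        )
        with pytest.raises(ValueError):
            weak_multifractality_fit(tf)
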