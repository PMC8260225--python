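"""Fisher axes, participation ratio, closed-form newborn geometry."""

import numpy as np
import pytest

from neurogen import (analytic_early_geometry, fisher_axes,
                      participation_ratio, quasi_orthogonality)
from neurogen.network import NetworkConfig, batch_rates, init_network


class TestFisherAxes:

    @pytest.fixture
    def isotropic_two_class(self):
        rng = np.random.default_rng(1)
        A = np.vstack([rng.normal(0, 1, (300, 5)) + [4, 0, 0, 0, 0],
                       rng.normal(0, 1, (300, 5))])
        return A, np.repeat([0, 1], 300)

    def test_isotropic_axis_parallel_to_mean_difference(self,
                                                        isotropic_two_class):
        A, y = isotropic_two_class
        fa = fisher_axes(A, y, [(0, 1)])
        diff = A[y == 0].mean(axis=0) - A[y == 1].mean(axis=0)
        cos = abs(fa.axes[0] @ diff / np.linalg.norm(diff))
        assert cos > 0.99

    def test_matches_sklearn_lda(self, isotropic_two_class):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        A, y = isotropic_two_class
        fa = fisher_axes(A, y, [(0, 1)])
        lda = LinearDiscriminantAnalysis(solver="eigen").fit(A, y)
        v = lda.coef_[0] / np.linalg.norm(lda.coef_[0])
        assert abs(fa.axes[0] @ v) > 0.999

    def test_pool_mean_projects_to_origin(self, isotropic_two_class):
        A, y = isotropic_two_class
        fa = fisher_axes(A, y, [(0, 1)])
        assert abs(fa.project(A).mean()) < 1e-9

    def test_scale_invariance_up_to_sign(self, isotropic_two_class):
        A, y = isotropic_two_class
        a1 = fisher_axes(A, y, [(0, 1)]).axes[0]
        a2 = fisher_axes(7.3 * A, y, [(0, 1)]).axes[0]
        assert abs(a1 @ a2) == pytest.approx(1.0, abs=1e-9)

    def test_singular_scatter_requires_regularization(self):
        A = np.zeros((8, 3))
        A[:4, 0] = [1, 1.0001, 1, 1.0001]     # variance only along one axis
        y = np.repeat([0, 1], 4)
        with pytest.raises(np.linalg.LinAlgError):
            fisher_axes(A, y, [(0, 1)], regularize=False)
        fa = fisher_axes(A, y, [(0, 1)])       # regularized path succeeds
        assert np.isfinite(fa.axes).all()

    def test_separability_improves_across_gaba_switch(self, similar_run,
                                                      tiny_similar):
        # population projections of the novel class separate better at the
        # end of the late (competitive) phase than at the end of the early
        # (cooperative) phase
        _, train, test = tiny_similar
        _, cfg, result = similar_run
        pairs = [(0, 2), (1, 2)]

        def axis_separation(state):
            A_tr = batch_rates(state, train.X, cfg)
            A_te = batch_rates(state, test.X, cfg)
            fa = fisher_axes(A_tr, train.labels, pairs)
            P = fa.project(A_te)
            js = []
            for ax, (m, n) in enumerate(pairs):
                pm, pn = P[test.labels == m, ax], P[test.labels == n, ax]
                js.append((pm.mean() - pn.mean()) ** 2
                          / (pm.var() + pn.var() + 1e-12))
            return np.array(js)

        j_early = axis_separation(result.state_snapshots["early"])
        j_late = axis_separation(result.state_snapshots["late"])
        assert np.all(j_late >= j_early)


class TestParticipationRatio:

    def test_isotropic_data_has_full_dimension(self):
        X = np.random.default_rng(0).normal(0, 1, (20000, 8))
        assert participation_ratio(X) == pytest.approx(8.0, rel=0.02)

    def test_rank_one_data(self):
        t = np.linspace(-1, 1, 50)
        X = np.outer(t, [1.0, 2.0, 3.0])
        assert participation_ratio(X) == pytest.approx(1.0)

    def test_rotation_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (500, 6)) * np.array([3, 2, 1, 1, 0.5, 0.1])
        Q, _ = np.linalg.qr(rng.normal(0, 1, (6, 6)))
        pr = participation_ratio(X)
        assert participation_ratio(X @ Q) == pytest.approx(pr, rel=1e-9)
        assert participation_ratio(5.0 * X) == pytest.approx(pr, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio(np.ones((1, 3)))
        with pytest.raises(ValueError):
            participation_ratio(np.ones((5, 3)))   # zero variance


class TestAnalyticGeometry:

    def test_similar_case_published_values(self):
        geo = analytic_early_geometry(0.2, 1.49, "similar")
        assert geo.norm == pytest.approx(1.47, abs=0.005)
        assert geo.phi_deg == pytest.approx(9.21, abs=0.01)

    def test_distinct_case_published_values(self):
        geo = analytic_early_geometry(0.8, 1.49, "distinct")
        assert geo.norm == pytest.approx(1.34, abs=0.005)
        assert geo.phi_deg == pytest.approx(47.2, abs=0.05)

    def test_coincident_limit(self):
        geo = analytic_early_geometry(1e-8, 1.49, "similar")
        assert geo.norm == pytest.approx(1.49)
        assert geo.phi_deg == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("case", ["similar", "distinct"])
    @pytest.mark.parametrize("xi", [0.1, 0.2, 0.5, 0.8, 0.95])
    def test_geometry_invariants(self, case, xi):
        geo = analytic_early_geometry(xi, 1.49, case)
        assert 0.0 <= geo.phi_deg <= 90.0
        assert 0.0 < geo.norm <= 1.49

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            analytic_early_geometry(0.2, -1.0, "similar")
        with pytest.raises(ValueError):
            analytic_early_geometry(1.2, 1.49, "similar")
        with pytest.raises(ValueError):
            analytic_early_geometry(0.2, 1.49, "sideways")

    def test_simulation_matches_analytics_at_end_of_early_phase(self,
                                                                toy_train):
        # the measured newborn norm and angle at the GABA-switch agree with
        # the closed-form construction evaluated at the measured mature norm
        from neurogen import (SimpleNetConfig, pretrain_mature_pair,
                              run_simple_neurogenesis)
        _, train, _ = toy_train
        _, mature_norm = pretrain_mature_pair(train, seed=1)
        traj = run_simple_neurogenesis(train, SimpleNetConfig(ramp_len=1000),
                                       seed=1)
        geo = analytic_early_geometry(0.2, mature_norm, "similar")
        assert traj.end_of_early_norm == pytest.approx(geo.norm, rel=0.02)
        assert abs(traj.end_of_early_phi - geo.phi_deg) < 1.0


class TestQuasiOrthogonality:

    def test_zero_weight_unit_with_positive_threshold(self):
        cfg = NetworkConfig(n_ec=4, n_dgc=2, n_inh=2)
        state = init_network(cfg, 0)
        state.W[0] = 0.0
        state.b[0] = 0.2
        x = np.array([1.0, 0, 0, 0])
        assert quasi_orthogonality(state, x, 0, cfg)

    def test_winner_for_own_pattern_is_not_orthogonal(self):
        cfg = NetworkConfig(n_ec=4, n_dgc=2, n_inh=2)
        state = init_network(cfg, 0)
        x = np.array([1.0, 0, 0, 0])
        state.W[0] = 5.0 * x
        state.b[0] = 0.5
        assert not quasi_orthogonality(state, x, 0, cfg)

    def test_reduces_to_orthogonality_without_inhibition_at_zero_threshold(
            self):
        cfg = NetworkConfig(n_ec=4, n_dgc=2, n_inh=0)
        state = init_network(cfg, 0)
        state.W[0] = [0.0, 0.0, 1.0, 0.0]
        state.b[0] = 0.0
        assert quasi_orthogonality(state, np.array([1.0, 0, 0, 0]), 0, cfg)
        assert not quasi_orthogonality(state, np.array([0.0, 0, 1, 0]), 0,
                                       cfg)
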