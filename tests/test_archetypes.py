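"""Tests for corner selection, model order selection and PCHA."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from action.archetypes import (
    ArchetypalAnalysis,
    CandidateSet,
    _min_volume_ellipsoid_sym,
    assign_dominant_archetype,
    detect_oversampling,
    pcha_fit,
    precondition_profiles,
    project_columns_to_simplex,
    select_num_archetypes,
    spa_select,
)
from action.simulate import simulate_separable_instance


class TestSPA:
    def test_corners_selected_before_interior_point(self):
        e1, e2 = np.eye(2)
        Y = np.column_stack([3 * e1, e2, 0.5 * (e1 + e2)])
        assert spa_select(Y, 2).indices == [0, 1]

    def test_k1_is_max_norm_column(self, rng):
        Y = rng.normal(size=(6, 10))
        assert spa_select(Y, 1).indices == [int(np.argmax(np.linalg.norm(Y, axis=0)))]

    def test_tie_broken_by_lowest_index(self):
        Y = np.column_stack([np.eye(3)[:, 1], np.eye(3)[:, 1], np.eye(3)[:, 0]])
        assert spa_select(Y, 1).indices == [0]

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_recovery_on_noiseless_separable(self, seed):
        Y, true_idx, _ = simulate_separable_instance(30, 4, 60, 0.0, seed)
        assert set(spa_select(Y, 4).indices) == set(true_idx)

    def test_degenerate_rank_returns_fewer_with_warning(self):
        Y = np.zeros((4, 5))
        Y[0, 0] = 1.0
        with pytest.warns(UserWarning, match="fewer"):
            cands = spa_select(Y, 3)
        assert cands.k == 1


class TestPreconditioning:
    def test_symmetric_basis_already_spherical(self):
        Y = np.column_stack([np.eye(3), -np.eye(3)])
        Yp, info = precondition_profiles(Y, 3)
        E = _min_volume_ellipsoid_sym(Yp, tol=1e-4)
        eig = np.linalg.eigvalsh(E)
        assert np.sqrt(eig.max() / eig.min()) <= 1.05

    def test_anisotropic_cloud_becomes_spherical(self, rng):
        Y = np.diag([10.0, 1.0]) @ rng.normal(size=(2, 200))
        Yp, _ = precondition_profiles(Y, 2)
        E = _min_volume_ellipsoid_sym(Yp, tol=1e-4)
        eig = np.linalg.eigvalsh(E)
        assert np.sqrt(eig.max() / eig.min()) <= 1.05

    @pytest.mark.parametrize("seed", range(5))
    def test_separable_support_invariant_under_transform(self, seed):
        Y, true_idx, _ = simulate_separable_instance(30, 4, 60, 0.0, seed)
        Yp, _ = precondition_profiles(Y, 4)
        assert set(spa_select(Yp, 4).indices) == set(true_idx)

    def test_rank_deficiency_reduces_target_with_warning(self, rng):
        Y = np.outer(rng.normal(size=6), rng.normal(size=10))  # rank 1
        with pytest.warns(UserWarning, match="rank"):
            Yp, info = precondition_profiles(Y, 3)
        assert info["rank"] == 1


class TestOversamplingDetection:
    def test_orthogonal_candidates_not_flagged(self):
        K = np.eye(4)  # orthogonal profiles: zero off-diagonal similarity
        flagged, graph = detect_oversampling(K, CandidateSet([0, 1, 2, 3]))
        assert not flagged and graph.edges == []

    def test_duplicated_candidate_flags_dense_pair(self, rng):
        Y = np.column_stack([np.eye(6)[:, :5] * 3.0, 3.0 * np.eye(6)[:, 0]])
        Y += 0.01 * rng.normal(size=Y.shape)
        K = Y.T @ Y
        flagged, graph = detect_oversampling(K, CandidateSet(list(range(6))))
        assert flagged
        assert any(set(e) == {0, 5} for e in graph.edges)

    def test_equal_similarities_give_no_edges(self):
        K = np.ones((5, 5))
        flagged, graph = detect_oversampling(K, CandidateSet(list(range(5))))
        assert not flagged and graph.edges == []

    def test_small_candidate_sets_never_flag(self):
        K = np.ones((3, 3)) + np.eye(3)
        flagged, _ = detect_oversampling(K, CandidateSet([0, 1, 2]))
        assert not flagged


class TestModelOrderSelection:
    def test_recovers_planted_type_count(self, fivetype, fivetype_kernel):
        Y = fivetype_kernel.weighted_profiles_
        k_star, _ = select_num_archetypes(Y, fivetype_kernel.kernel_, 2, 12)
        assert k_star == 5

    def test_unflagged_search_returns_kmax_with_warning(self, rng):
        Y = np.eye(8) * (2.0 + rng.random(8))  # mutually orthogonal cells
        K = Y.T @ Y
        with pytest.warns(UserWarning, match="k_max"):
            k_star, _ = select_num_archetypes(Y, K, 2, 4)
        assert k_star == 4

    def test_k_star_never_below_kmin(self, rng):
        Y = rng.normal(size=(10, 30))
        K = Y.T @ Y
        k_star, _ = select_num_archetypes(Y, K, 2, 8)
        assert k_star >= 2


class TestPCHA:
    def test_identity_init_reconstructs_exactly_when_k_equals_n(self, rng):
        Y = rng.normal(size=(6, 5))
        dec = pcha_fit(Y, CandidateSet(list(range(5))), 5)
        assert dec.objective_trace[0] <= 1e-8 * np.linalg.norm(Y)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_monotone_and_columns_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(12, 40))
        init = spa_select(Y, 4)
        dec = pcha_fit(Y, init, 4)
        trace = np.asarray(dec.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)
        assert np.abs(dec.C.sum(axis=0) - 1.0).max() <= 1e-9
        assert np.abs(dec.H.sum(axis=0) - 1.0).max() <= 1e-9
        assert dec.C.min() >= 0 and dec.H.min() >= 0

    def test_objective_bounded_below_by_rank_k_error(self, rng):
        Y = rng.normal(size=(10, 30))
        k = 3
        dec = pcha_fit(Y, spa_select(Y, k), k)
        s = np.linalg.svd(Y, compute_uv=False)
        best_rank_k = np.sqrt((s[k:] ** 2).sum())
        assert dec.objective_trace[-1] >= best_rank_k - 1e-8

    def test_recovers_planted_simplex_corners(self, rng):
        k, m, n = 4, 10, 200
        W = np.eye(m)[:, :k] * np.array([3.0, 2.0, 4.0, 2.5])
        H = rng.dirichlet(np.full(k, 0.3), size=n).T
        Y = W @ H
        dec = pcha_fit(Y, spa_select(Y, k), k)
        D = np.array(
            [[np.linalg.norm(dec.A[:, i] - W[:, j]) for j in range(k)]
             for i in range(k)]
        )
        r, c = linear_sum_assignment(D)
        rel_err = np.sqrt((D[r, c] ** 2).sum()) / np.linalg.norm(W)
        assert rel_err <= 0.05

    def test_reconstruction_stays_in_archetype_hull(self, rng):
        Y = rng.normal(size=(8, 25))
        dec = pcha_fit(Y, spa_select(Y, 3), 3)
        recon = dec.A @ dec.H
        # columns of H are convex weights, so the reconstruction is bounded
        # by the extreme archetype coordinates
        assert np.all(recon.max(axis=1) <= dec.A.max(axis=1) + 1e-9)
        assert np.all(recon.min(axis=1) >= dec.A.min(axis=1) - 1e-9)


class TestSimplexProjection:
    def test_projects_to_stochastic_columns(self, rng):
        V = rng.normal(size=(6, 20)) * 3
        P = project_columns_to_simplex(V)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)
        assert P.min() >= 0

    def test_identity_on_simplex_points(self, rng):
        V = rng.dirichlet(np.ones(5), size=8).T
        np.testing.assert_allclose(project_columns_to_simplex(V), V, atol=1e-12)


class TestDominantArchetype:
    def test_pure_cell(self):
        assert assign_dominant_archetype(np.array([[0.0], [1.0]]))[0] == 1

    def test_tie_breaks_to_lowest_index(self):
        assert assign_dominant_archetype(np.array([[0.5], [0.5]]))[0] == 0

    def test_cell_permutation_equivariance(self, fivetype, fivetype_kernel):
        from action.evaluate import clustering_scores

        Y = fivetype_kernel.weighted_profiles_[:, :150]
        rng = np.random.default_rng(0)
        perm = rng.permutation(Y.shape[1])
        aa1 = ArchetypalAnalysis(n_archetypes=4).fit(Y.T)
        aa2 = ArchetypalAnalysis(n_archetypes=4).fit(Y[:, perm].T)
        assert clustering_scores(aa2.labels_, aa1.labels_[perm])["ari"] == 1.0


class TestArchetypalAnalysisEstimator:
    def test_fit_exposes_sklearn_style_attributes(self, fivetype, fivetype_kernel):
        aa = ArchetypalAnalysis(k_max=10).fit(fivetype_kernel.weighted_profiles_.T)
        n = fivetype.X.n_cells
        assert aa.n_archetypes_ == 5
        assert aa.C_.shape == (n, 5) and aa.H_.shape == (5, n)
        assert aa.archetypes_.shape == (5, fivetype.X.n_genes)
        assert aa.labels_.shape == (n,)

    def test_transform_returns_convex_coefficients(self, fivetype_kernel):
        Y = fivetype_kernel.weighted_profiles_
        aa = ArchetypalAnalysis(n_archetypes=5).fit(Y.T)
        Ht = aa.transform(Y[:, :20].T)
        np.testing.assert_allclose(Ht.sum(axis=1), 1.0, atol=1e-8)
        assert Ht.min() >= -1e-12
        # training cells should be assigned consistently with fit labels
        assert (aa.predict(Y[:, :20].T) == aa.labels_[:20]).mean() >= 0.9
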