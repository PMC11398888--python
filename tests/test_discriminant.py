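"""The penalized discriminant estimator: auxiliary coding, Gram matrix,
augmented system, solver-versus-oracle agreement, scoring, thresholds,
AUC and model selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fosda import (FitConfig, FoSDesign, FunctionalLDA, GramMatrix,
                   KernelSpec, VelocityField, auc, auxiliary_responses,
                   build_augmented_system, choose_threshold, gram_matrix,
                   select_lambdas, solve_augmented)
from fosda.experiments import dense_oracle_solution, fit_maps_only
from fosda.representation import gaussian_kernel
from fosda.simulate import SimulationScenario, simulate_maps


# ---------------------------------------------------------------------------
# Auxiliary responses
# ---------------------------------------------------------------------------

class TestAuxiliaryResponses:
    def test_balanced_example(self):
        resp = auxiliary_responses(np.array([1, 1, 2, 2]))
        np.testing.assert_allclose(resp.y, [-2, -2, 2, 2])

    def test_unbalanced_example(self):
        resp = auxiliary_responses(np.array([1, 2, 2, 2]))
        np.testing.assert_allclose(resp.y, [-4, 4 / 3, 4 / 3, 4 / 3])

    @given(st.lists(st.sampled_from([0, 1]), min_size=2, max_size=60)
           .filter(lambda ls: len(set(ls)) == 2))
    def test_zero_mean_for_any_labeling(self, labels):
        resp = auxiliary_responses(np.array(labels))
        assert abs(resp.y.sum()) < 1e-10 * len(labels)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="2 classes"):
            auxiliary_responses(np.ones(5))


# ---------------------------------------------------------------------------
# Gram matrix
# ---------------------------------------------------------------------------

class TestGramMatrix:
    kernel = KernelSpec(sigma=1.0)

    def _field(self, control, coeffs):
        return VelocityField(control_points=control,
                             coefficients=np.asarray(coeffs, float),
                             kernel=self.kernel)

    def test_single_quad_point_reduces_to_dot_product(self, rng):
        control = rng.standard_normal((4, 3))
        v1 = self._field(control, rng.standard_normal((4, 3)))
        v2 = self._field(control, rng.standard_normal((4, 3)))
        p = rng.standard_normal((1, 3))
        g = gram_matrix([v1, v2], self.kernel, p, np.ones(1)).sigma
        assert np.isclose(g[0, 1], float(v1(p)[0] @ v2(p)[0]))

    def test_zero_field_zeroes_row_and_column(self, rng):
        control = rng.standard_normal((4, 3))
        v1 = self._field(control, rng.standard_normal((4, 3)))
        v0 = self._field(control, np.zeros((4, 3)))
        quad = rng.standard_normal((6, 3))
        g = gram_matrix([v1, v0], self.kernel, quad, np.ones(6)).sigma
        assert np.abs(g[1]).max() == 0.0 and np.abs(g[:, 1]).max() == 0.0

    def test_two_point_hand_computed_value(self):
        # fields constant on the quadrature set, values u and w
        quad = np.array([[0.0, 0, 0], [0.7, 0, 0]])
        K = gaussian_kernel(self.kernel, quad, quad)
        u = np.array([1.0, -2.0, 0.5])
        w = np.array([0.3, 1.1, -0.4])
        alpha_u = np.linalg.solve(K, np.tile(u, (2, 1)))
        alpha_w = np.linalg.solve(K, np.tile(w, (2, 1)))
        vu = self._field(quad, alpha_u)
        vw = self._field(quad, alpha_w)
        g = gram_matrix([vu, vw], self.kernel, quad, np.ones(2)).sigma
        expected = float(u @ w) * (2.0 + 2.0 * np.exp(-0.49))
        assert np.isclose(g[0, 1], expected)

    def test_kernel_mismatch(self, rng):
        control = rng.standard_normal((3, 3))
        v = self._field(control, rng.standard_normal((3, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            gram_matrix([v], KernelSpec(sigma=2.0), control, np.ones(3))


# ---------------------------------------------------------------------------
# Augmented system and solver
# ---------------------------------------------------------------------------

def _random_bivariate_instance(ops, n, rng):
    kernel = KernelSpec(sigma=0.8)
    control = ops.mesh.vertices[rng.choice(ops.n_vertices, 20,
                                           replace=False)]
    vels = tuple(VelocityField(control_points=control,
                               coefficients=0.1 * rng.standard_normal(
                                   (20, 3)),
                               kernel=kernel) for _ in range(n))
    maps = rng.standard_normal((n, ops.n_vertices))
    labels = np.repeat([1, 2], n // 2)
    return vels, maps, labels


class TestAugmentedSystem:
    def test_block_dimensions_with_shrinkage(self, ops1, rng):
        n, s = 8, ops1.n_vertices
        vels, maps, labels = _random_bivariate_instance(ops1, n, rng)
        resp = auxiliary_responses(labels)
        config = FitConfig(lambda1=0.5, lambda2=0.2, epsilon=ops1.epsilon)
        sigma = gram_matrix(vels, vels[0].kernel, vels[0].control_points,
                            np.ones(20))
        A, rhs = build_augmented_system(sigma, maps, ops1, config, resp)
        assert A.shape == (n + 2 * s + n, n + s)
        assert rhs.shape == (n + 2 * s + n,)
        assert np.all(rhs[n:] == 0)

    def test_normal_equations_match_analytic_blocks(self, ops1, rng):
        n = 8
        vels, maps, labels = _random_bivariate_instance(ops1, n, rng)
        resp = auxiliary_responses(labels)
        config = FitConfig(lambda1=0.7, lambda2=0.3, epsilon=ops1.epsilon)
        sigma = gram_matrix(vels, vels[0].kernel, vels[0].control_points,
                            np.ones(20)).sigma
        A, rhs = build_augmented_system(GramMatrix(sigma=sigma), maps, ops1,
                                        config, resp)
        AtA = (A.T @ A).toarray()
        M = ops1.mass.toarray()
        D = (ops1.stiffness @ np.diag(1.0 / ops1.lumped_mass)
             @ ops1.stiffness.toarray() + config.epsilon * M)
        XM = maps @ M
        jitter = 1e-10 * np.trace(sigma) / n
        expected = np.block([
            [sigma @ sigma + config.lambda1 * (sigma
                                               + jitter * np.eye(n)),
             sigma @ XM],
            [XM.T @ sigma, XM.T @ XM + config.lambda2 * D],
        ])
        assert (np.abs(AtA - expected).max()
                <= 1e-10 * np.abs(expected).max())

    def test_zero_gram_reduces_to_univariate_problem(self, ops1, rng):
        n, s = 10, ops1.n_vertices
        maps = rng.standard_normal((n, s))
        labels = np.repeat([1, 2], 5)
        resp = auxiliary_responses(labels)
        config = FitConfig(lambda1=1.0, lambda2=0.1, epsilon=ops1.epsilon,
                           solver_tol=1e-12)
        sigma = GramMatrix(sigma=np.zeros((n, n)))
        A, rhs = build_augmented_system(sigma, maps, ops1, config, resp)
        both = solve_augmented(A, rhs, config)
        A_uni, rhs_uni = build_augmented_system(None, maps, ops1, config,
                                                resp)
        uni = solve_augmented(A_uni, rhs_uni, config)
        assert np.abs(both[:n]).max() < 1e-8
        np.testing.assert_allclose(both[n:], uni, atol=1e-8)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            FitConfig(lambda1=0.0, lambda2=1.0)


class TestSolver:
    def test_agrees_with_dense_normal_equations(self, ops2, rng):
        n = 40
        vels, maps, labels = _random_bivariate_instance(ops2, n, rng)
        est = FunctionalLDA(operators=ops2, lambda1=0.5, lambda2=0.05,
                            solver_tol=1e-12)
        est.fit(FoSDesign(maps=maps, velocities=vels), labels)
        Xc = maps - maps.mean(axis=0)
        config = est._config()
        oracle = dense_oracle_solution(est.gram_.sigma, Xc, ops2, config,
                                       auxiliary_responses(labels).y)
        got = np.concatenate([est.coef_geometry_, est.coef_map_])
        rel = np.linalg.norm(got - oracle) / np.linalg.norm(oracle)
        assert rel < 1e-6

    def test_penalty_domination_shrinks_solution(self, sphere1, rng):
        from fosda import assemble_penalty
        # unit shrinkage weight so the l2 floor of the penalty is O(1)
        ops = assemble_penalty(sphere1, epsilon=1.0)
        n = 10
        vels, maps, labels = _random_bivariate_instance(ops, n, rng)
        design = FoSDesign(maps=maps, velocities=vels)

        def norms(lam):
            est = FunctionalLDA(operators=ops, lambda1=lam, lambda2=lam,
                                solver_tol=1e-12).fit(design, labels)
            return (np.linalg.norm(est.coef_geometry_),
                    np.linalg.norm(est.coef_map_))

        gat1, mat1 = norms(1.0)
        gat6, mat6 = norms(1e6)
        assert gat6 < 1e-4 * gat1
        assert mat6 < 1e-4 * mat1

    def test_permutation_equivariance(self, ops1, rng):
        n = 12
        vels, maps, labels = _random_bivariate_instance(ops1, n, rng)
        perm = rng.permutation(n)
        est = FunctionalLDA(operators=ops1, lambda1=0.3, lambda2=0.05,
                            solver_tol=1e-12)
        a = est.fit(FoSDesign(maps=maps, velocities=vels), labels)
        cG, cF = a.coef_geometry_.copy(), a.coef_map_.copy()
        b = FunctionalLDA(operators=ops1, lambda1=0.3, lambda2=0.05,
                          solver_tol=1e-12).fit(
            FoSDesign(maps=maps[perm],
                      velocities=tuple(vels[i] for i in perm)),
            labels[perm])
        np.testing.assert_allclose(b.coef_geometry_, cG[perm], atol=1e-8)
        np.testing.assert_allclose(b.coef_map_, cF, atol=1e-8)

    def test_objective_optimality_under_perturbations(self, ops1, rng):
        n = 10
        vels, maps, labels = _random_bivariate_instance(ops1, n, rng)
        est = FunctionalLDA(operators=ops1, lambda1=0.5, lambda2=0.1,
                            solver_tol=1e-12)
        est.fit(FoSDesign(maps=maps, velocities=vels), labels)
        sigma = est.gram_.sigma
        Xc = maps - maps.mean(axis=0)
        y = auxiliary_responses(labels).y
        M = ops1.mass.toarray()
        D = (ops1.stiffness @ np.diag(1.0 / ops1.lumped_mass)
             @ ops1.stiffness.toarray() + ops1.epsilon * M)
        XM = Xc @ M

        def objective(cG, cF):
            resid = y - sigma @ cG - XM @ cF
            return (resid @ resid + 0.5 * (cG @ (sigma @ cG))
                    + 0.1 * (cF @ (D @ cF)))

        base = objective(est.coef_geometry_, est.coef_map_)
        for _ in range(50):
            dG = 1e-3 * rng.standard_normal(n)
            dF = 1e-3 * rng.standard_normal(ops1.n_vertices)
            assert objective(est.coef_geometry_ + dG,
                             est.coef_map_ + dF) >= base - 1e-9 * abs(base)


# ---------------------------------------------------------------------------
# Fitting behaviour on simulated data
# ---------------------------------------------------------------------------

class TestFitBehaviour:
    def test_univariate_reduction_matches_direct_penalized_solve(self, ops1,
                                                                 rng):
        n = 12
        maps = rng.standard_normal((n, ops1.n_vertices))
        labels = np.repeat([1, 2], 6)
        est = fit_maps_only(maps, labels, ops1, lambda2=0.05,
                            solver_tol=1e-12)
        Xc = maps - maps.mean(axis=0)
        oracle = dense_oracle_solution(
            None, Xc, ops1, FitConfig(lambda2=0.05, epsilon=ops1.epsilon),
            auxiliary_responses(labels).y)
        np.testing.assert_allclose(est.coef_map_, oracle, rtol=1e-6,
                                   atol=1e-10)

    def test_recovered_sign_matches_class_coding(self, ops2):
        scenario = SimulationScenario(level=2, seed=0)
        labels = np.repeat([1, 2], 25)
        signs = []
        for r in range(10):
            rng_r = np.random.default_rng([r, 11])
            maps, gt = simulate_maps(ops2, scenario, labels, rng_r)
            X = np.stack([m.values for m in maps])
            est = fit_maps_only(X, labels, ops2, lambda2=1e-3,
                                solver_tol=1e-8)
            signs.append(np.sign(est.coef_map_
                                 @ (ops2.mass @ gt.contrast)))
        assert signs == [1.0] * 10

    def test_roughness_monotone_in_penalty(self, ops1, rng):
        n = 16
        maps = rng.standard_normal((n, ops1.n_vertices))
        labels = np.repeat([1, 2], 8)
        roughness = []
        for lam in (0.01, 0.02, 0.04):
            est = fit_maps_only(maps, labels, ops1, lambda2=lam,
                                solver_tol=1e-12)
            c = est.coef_map_
            roughness.append(c @ (ops1.penalty @ c))
        assert roughness[0] >= roughness[1] >= roughness[2]

    def test_degenerate_training_data_rejected(self, ops1):
        maps = np.tile(np.ones(ops1.n_vertices), (6, 1))
        with pytest.raises(ValueError, match="degenerate"):
            FunctionalLDA(operators=ops1).fit(maps, np.repeat([1, 2], 3))

    def test_centering_invariance(self, ops1, rng):
        n = 14
        maps = rng.standard_normal((n, ops1.n_vertices))
        test_maps = rng.standard_normal((4, ops1.n_vertices))
        labels = np.repeat([1, 2], 7)
        a = fit_maps_only(maps, labels, ops1, 0.05, solver_tol=1e-12)
        b = fit_maps_only(maps + 7.5, labels, ops1, 0.05, solver_tol=1e-12)
        np.testing.assert_allclose(a.decision_function(test_maps),
                                   b.decision_function(test_maps + 7.5),
                                   atol=1e-8)


class TestScoring:
    def test_score_at_the_training_means_is_zero(self, ops1, rng):
        n = 10
        vels, maps, labels = _random_bivariate_instance(ops1, n, rng)
        est = FunctionalLDA(operators=ops1, lambda1=0.5, lambda2=0.1)
        est.fit(FoSDesign(maps=maps, velocities=vels), labels)
        mean_design = FoSDesign(maps=est.map_mean_[None, :],
                                velocities=(est.velocity_mean_,))
        assert abs(est.decision_function(mean_design)[0]) < 1e-10

    def test_zero_geometry_coefficients_reduce_to_map_term(self, ops1, rng):
        n = 10
        vels, maps, labels = _random_bivariate_instance(ops1, n, rng)
        est = FunctionalLDA(operators=ops1, lambda1=0.5, lambda2=0.1)
        est.fit(FoSDesign(maps=maps, velocities=vels), labels)
        est.coef_geometry_ = np.zeros(n)
        scores = est.decision_function(FoSDesign(maps=maps,
                                                 velocities=vels))
        manual = (maps - est.map_mean_) @ (ops1.mass @ est.coef_map_)
        np.testing.assert_allclose(scores, manual, atol=1e-12)

    def test_class_means_ordered_on_held_out_data(self, ops2):
        scenario = SimulationScenario(level=2, seed=0)
        labels = np.repeat([1, 2], 30)
        rng_r = np.random.default_rng(3)
        maps_tr, _ = simulate_maps(ops2, scenario, labels, rng_r)
        maps_te, _ = simulate_maps(ops2, scenario, labels, rng_r)
        Xtr = np.stack([m.values for m in maps_tr])
        Xte = np.stack([m.values for m in maps_te])
        est = fit_maps_only(Xtr, labels, ops2, 1e-3, solver_tol=1e-8)
        scores = est.decision_function(Xte)
        assert scores[labels == 2].mean() > scores[labels == 1].mean()


# ---------------------------------------------------------------------------
# Threshold, AUC, model selection
# ---------------------------------------------------------------------------

class TestThreshold:
    def test_perfect_separation_gives_gap_midpoint(self):
        scores = np.array([-3.0, -2.0, 1.0, 4.0])
        labels = np.array([1, 1, 2, 2])
        assert choose_threshold(scores, labels) == pytest.approx(-0.5)

    def test_all_equal_scores_error(self):
        with pytest.raises(ValueError, match="no discriminating"):
            choose_threshold(np.ones(4), np.array([1, 1, 2, 2]))

    def test_label_swap_negates_the_rule(self, rng):
        scores = rng.standard_normal(40)
        labels = np.repeat([1, 2], 20)
        scores[labels == 2] += 1.0
        t = choose_threshold(scores, labels)
        t_swapped = choose_threshold(-scores, np.where(labels == 1, 2, 1))
        assert t_swapped == pytest.approx(-t)

    def test_fixed_specificity(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0])
        labels = np.array([1, 1, 1, 1, 2, 2])
        t = choose_threshold(scores, labels, ("fixed_specificity", 1.0))
        assert t == pytest.approx(6.5)


class TestAUC:
    def test_perfect_separation(self):
        assert auc(np.array([1, 2, 8, 9.0]),
                   np.array([1, 1, 2, 2])) == 1.0

    def test_independent_scores_near_half(self, rng):
        scores = rng.standard_normal(2000)
        labels = np.repeat([1, 2], 1000)
        assert abs(auc(scores, labels) - 0.5) < 0.05

    @given(st.integers(0, 1000))
    def test_negation_flips_auc(self, seed):
        r = np.random.default_rng(seed)
        scores = r.standard_normal(30)
        labels = np.repeat([1, 2], 15)
        assert auc(scores, labels) == pytest.approx(
            1.0 - auc(-scores, labels))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc(np.ones(3), np.ones(3))


class TestSelectLambdas:
    def _data(self, ops, n, seed):
        scenario = SimulationScenario(level=2, seed=0)
        labels = np.repeat([1, 2], n // 2)
        maps, _ = simulate_maps(ops, scenario, labels,
                                np.random.default_rng(seed))
        return np.stack([m.values for m in maps]), labels

    def test_single_point_grid(self, ops2):
        Xtr, ytr = self._data(ops2, 20, 0)
        Xva, yva = self._data(ops2, 20, 1)
        best, table = select_lambdas((Xtr, ytr), (Xva, yva), [(1.0, 0.01)],
                                     ops2, solver_tol=1e-8)
        assert (best.lambda1, best.lambda2) == (1.0, 0.01)
        assert len(table) == 1

    def test_table_has_one_row_per_grid_point(self, ops2):
        Xtr, ytr = self._data(ops2, 20, 0)
        Xva, yva = self._data(ops2, 20, 1)
        grid = [(l1, l2) for l1 in (0.1, 1.0) for l2 in (1e-4, 1e-2, 1.0)]
        _, table = select_lambdas((Xtr, ytr), (Xva, yva), grid, ops2,
                                  solver_tol=1e-8)
        assert len(table) == len(grid)

    def test_smooth_truth_selects_nontrivial_penalty(self, ops2):
        # with a smooth generating direction, the tiny penalty overfits
        selected = []
        for r in range(10):
            Xtr, ytr = self._data(ops2, 40, 100 + r)
            Xva, yva = self._data(ops2, 40, 200 + r)
            best, _ = select_lambdas((Xtr, ytr), (Xva, yva),
                                     [(1.0, 1e-9), (1.0, 1e-3)], ops2,
                                     solver_tol=1e-8)
            selected.append(best.lambda2)
        assert np.median(selected) > 1e-9

    def test_empty_grid_errors(self, ops2):
        with pytest.raises(ValueError, match="empty"):
            select_lambdas((None, None), (None, None), [], ops2)
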