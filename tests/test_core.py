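"""Unit and property tests for the joint model and the descent optimizer."""

import numpy as np
import pytest

from pgxtl.core import (
    DescentDivergenceError,
    DescentSettings,
    EffectPair,
    StandardizeStats,
    StrategyConfig,
    compute_prs,
    descent_step,
    penalized_loss,
    residualize,
    run_descent,
    standardize_genotypes,
)
from tests.conftest import make_cohort, make_genotypes


class TestResidualize:
    def test_two_arm_means_removed(self):
        res = residualize(np.array([1.0, 2, 3, 4]), None, np.array([0, 0, 1, 1.0]))
        np.testing.assert_allclose(res, [-0.5, 0.5, -0.5, 0.5], atol=1e-12)

    def test_perfectly_explained_response_gives_zero_residuals(self):
        t = np.array([0, 1, 0, 1.0])
        res = residualize(2.0 * t, None, t)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            residualize(np.full(4, 5.0), None, np.array([0, 0, 1, 1.0]))

    def test_collinear_covariate_named(self, rng):
        t = np.array([0.0, 0, 1, 1, 0, 1])
        y = rng.normal(size=6)
        with pytest.raises(ValueError, match="treatment"):
            residualize(y, t[:, None], t)  # covariate duplicates treatment

    def test_residuals_orthogonal_to_design(self, rng):
        n = 40
        cov = rng.normal(size=(n, 3))
        t = (rng.random(n) < 0.5).astype(float)
        y = rng.normal(size=n)
        res = residualize(y, cov, t)
        assert abs(res.sum()) < 1e-8
        assert abs(res @ t) < 1e-8
        np.testing.assert_allclose(cov.T @ res, 0.0, atol=1e-8)

    def test_fold_hygiene_apply(self, rng):
        n = 30
        t = (rng.random(n) < 0.5).astype(float)
        y = rng.normal(size=n) + t
        res, coef, apply = residualize(y, None, t, return_model=True)
        np.testing.assert_allclose(apply(y, None, t), res, atol=1e-12)


class TestStandardize:
    def test_symmetric_column(self):
        z, stats = standardize_genotypes(np.array([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(z[:, 0], [-1, 0, 1])
        assert stats.mean[0] == 1 and stats.sd[0] == 1

    def test_zero_variance_flagged(self):
        z, stats = standardize_genotypes(np.full((3, 1), 2.0))
        np.testing.assert_array_equal(z, 0.0)
        assert stats.zero_variance[0]

    def test_reference_stats_affine_rule(self):
        ref = StandardizeStats(np.array([1.0]), np.array([1.0]))
        z, _ = standardize_genotypes(np.array([[3.0]]), ref)
        assert z[0, 0] == 2.0


class TestPenalizedLoss:
    def test_zero_weights_give_sum_of_squares(self, rng):
        y = rng.normal(size=6)
        x = rng.normal(size=(6, 4))
        b = np.zeros(4)
        assert penalized_loss(b, x, y, 0.3) == pytest.approx(y @ y)

    def test_unpenalized_loss_at_ols_equals_rss(self, rng):
        x = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        b = np.linalg.solve(x.T @ x, x.T @ y)  # normal-equations oracle
        rss = float(np.sum((y - x @ b) ** 2))
        assert penalized_loss(b, x, y, 0.0) == pytest.approx(rss, rel=1e-12)

    def test_penalty_contribution(self, rng):
        x = rng.normal(size=(5, 2))
        b = np.array([2.0, 0.0])  # ||b||^2 = 4
        y = np.zeros(5)
        expected = float(np.sum((x @ b) ** 2)) + 0.5 * 4
        assert penalized_loss(b, x, y, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="design"):
            penalized_loss(np.zeros(3), rng.normal(size=(4, 2)), rng.normal(size=4), 0.0)


def _pair(bg, bgt):
    bg, bgt = np.atleast_1d(bg), np.atleast_1d(bgt)
    ids = np.asarray([f"v{j}" for j in range(len(bg))], dtype=object)
    return EffectPair(bg, bgt, ids)


class TestDescentStep:
    def test_identity_design_gradient(self):
        b = _pair([0.0], [0.0])
        x = np.eye(2)
        new = descent_step(b, x, np.array([2.0, 4.0]),
                           DescentSettings(0.1, 0.0, 1), StrategyConfig.from_name("M1"))
        np.testing.assert_allclose([new.beta_g[0], new.beta_gt[0]], [0.2, 0.4])

    def test_pure_shrinkage_limit(self):
        # learning rate ~0 isolates the (1 - lambda) shrinkage factor
        b = _pair([1.0], [1.0])
        new = descent_step(b, np.zeros((2, 2)), np.zeros(2),
                           DescentSettings(1e-300, 0.99, 1), StrategyConfig.from_name("M1"))
        np.testing.assert_allclose([new.beta_g[0], new.beta_gt[0]], [0.01, 0.01], atol=1e-12)

    def test_gt_only_freezes_prognostic_block(self):
        b = _pair([0.5], [0.0])
        x = np.eye(2)
        new = descent_step(b, x, np.array([2.0, 4.0]),
                           DescentSettings(0.1, 0.0, 1), StrategyConfig.from_name("M5"))
        assert new.beta_g[0] == 0.5
        assert new.beta_gt[0] != 0.0

    def test_reparameterization_consistency(self, rng):
        # the (eta_new, lam_new) update equals the raw-gradient update with
        # eta = eta_new / 2 and lam = lam_new / eta_new (since lam_new = 2 eta lam)
        x = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        bv = rng.normal(size=6)
        eta_new, lam_new = 0.03, 0.4
        b = _pair(bv[:3], bv[3:])
        new = descent_step(b, x, y, DescentSettings(eta_new, lam_new, 1),
                           StrategyConfig.from_name("M1"))
        eta = eta_new / 2
        lam = lam_new / eta_new
        grad = -2 * x.T @ (y - x @ bv) + 2 * lam * bv
        np.testing.assert_allclose(new.stacked, bv - eta * grad, rtol=1e-12)


class TestRunDescent:
    def test_single_iteration_matches_descent_step(self, rng):
        cohort = make_cohort(rng, 30, 4)
        pre = _pair(rng.normal(size=4), np.zeros(4))
        settings = DescentSettings(0.01, 0.5, 1)
        strat = StrategyConfig.from_name("M1")
        trace = run_descent(cohort, pre, settings, strat)
        # replicate the preprocessing by hand
        z, _ = standardize_genotypes(cohort.genotypes)
        x = np.hstack([z, z * cohort.treatment[:, None]])
        y = residualize(cohort.phenotype, None, cohort.treatment)
        step = descent_step(pre, x, y, settings, strat)
        np.testing.assert_allclose(trace.state(1).stacked, step.stacked, rtol=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.5])
    def test_converges_to_ridge_fixed_point(self, rng, lam):
        x = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        eta = 0.5 / np.linalg.eigvalsh(x.T @ x).max()
        bv = np.zeros(10)
        for _ in range(20000):
            bv = (1 - lam) * bv + eta * (x.T @ (y - x @ bv))
        oracle = np.linalg.solve(x.T @ x + (lam / eta) * np.eye(10), x.T @ y)
        np.testing.assert_allclose(bv, oracle, rtol=1e-8)

    def test_monotone_loss_without_penalty(self, rng):
        cohort = make_cohort(rng, 60, 5)
        pre = _pair(rng.normal(size=5), np.zeros(5))
        z, _ = standardize_genotypes(cohort.genotypes)
        x = np.hstack([z, z * cohort.treatment[:, None]])
        y = residualize(cohort.phenotype, None, cohort.treatment)
        eta = 1.9 / np.linalg.eigvalsh(x.T @ x).max()
        trace = run_descent(cohort, pre, DescentSettings(eta, 0.0, 40),
                            StrategyConfig.from_name("M1"))
        losses = [penalized_loss(s, x, y, 0.0) for s in trace.states]
        assert all(l2 <= l1 + 1e-9 for l1, l2 in zip(losses, losses[1:]))

    @pytest.mark.parametrize("name", ["M5", "M6"])
    def test_gt_only_strategies_never_move_prognostic_block(self, rng, name):
        cohort = make_cohort(rng, 40, 6)
        pre = _pair(rng.normal(size=6), np.zeros(6))
        trace = run_descent(cohort, pre, DescentSettings(0.005, 0.5, 15),
                            StrategyConfig.from_name(name))
        for state in trace.states:
            np.testing.assert_array_equal(state.beta_g, pre.beta_g)

    def test_divergence_reports_iteration(self, rng):
        cohort = make_cohort(rng, 40, 6)
        pre = _pair(rng.normal(size=6), np.zeros(6))
        with pytest.raises(DescentDivergenceError) as err:
            run_descent(cohort, pre, DescentSettings(50.0, 0.0, 30),
                        StrategyConfig.from_name("M1"))
        assert err.value.iteration >= 1

    def test_sparse_pre_weights_restrict_active_set(self, rng):
        cohort = make_cohort(rng, 40, 8)
        beta = np.zeros(8)
        beta[[1, 4]] = [0.3, -0.2]
        trace = run_descent(cohort, _pair(beta, np.zeros(8)),
                            DescentSettings(0.01, 0.0, 3), StrategyConfig.from_name("M1"))
        assert list(trace.variant_ids) == ["v1", "v4"]


class TestStrategyConfig:
    def test_table_semantics(self):
        m5 = StrategyConfig.from_name("M5")
        assert m5.update_mode == "gt_only" and m5.tuning_criterion == "overall_r2"
        assert StrategyConfig.from_name("M3").tuning_criterion == "conditional_r2"
        with pytest.raises(ValueError):
            StrategyConfig.from_name("M9")
        with pytest.raises(ValueError):
            StrategyConfig("M5", "both", "zero", "overall_r2")


class TestComputePrs:
    def test_zero_effects_zero_scores(self, rng):
        g = make_genotypes(rng, 10, 3)
        pg, pgt = compute_prs(g, _pair(np.zeros(3), np.zeros(3)))
        np.testing.assert_array_equal(pg, 0.0)
        np.testing.assert_array_equal(pgt, 0.0)

    def test_single_snp_scalar_product(self):
        z = np.array([[-1.0], [0.0], [1.0]])
        effects = _pair([2.0], [-1.0])
        pg, pgt = compute_prs(z, effects, variant_ids=np.array(["v0"]))
        np.testing.assert_allclose(pg, [-2, 0, 2])
        np.testing.assert_allclose(pgt, [1, 0, -1])

    def test_weight_order_irrelevant(self, rng):
        g = make_genotypes(rng, 12, 5)
        bg, bgt = rng.normal(size=5), rng.normal(size=5)
        ids = np.asarray([f"v{j}" for j in range(5)], dtype=object)
        perm = rng.permutation(5)
        direct = compute_prs(g, EffectPair(bg, bgt, ids))
        shuffled = compute_prs(g, EffectPair(bg[perm], bgt[perm], ids[perm]))
        np.testing.assert_allclose(direct[0], shuffled[0], rtol=1e-12)
        np.testing.assert_allclose(direct[1], shuffled[1], rtol=1e-12)

    def test_scaling_equivariance(self, rng):
        g = make_genotypes(rng, 8, 4)
        bg, bgt = rng.normal(size=4), rng.normal(size=4)
        ids = np.asarray([f"v{j}" for j in range(4)], dtype=object)
        base = compute_prs(g, EffectPair(bg, bgt, ids))
        scaled = compute_prs(g, EffectPair(3.0 * bg, 3.0 * bgt, ids))
        np.testing.assert_allclose(scaled[0], 3.0 * base[0], rtol=1e-12)
        np.testing.assert_allclose(scaled[1], 3.0 * base[1], rtol=1e-12)

    def test_empty_intersection_rejected(self, rng):
        g = make_genotypes(rng, 5, 2)
        other = EffectPair(np.ones(2), np.ones(2), np.asarray(["x1", "x2"], dtype=object))
        with pytest.raises(ValueError, match="shared"):
            compute_prs(g, other)
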