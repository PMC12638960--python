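"""Tests for fold assignment, grid tuning and nested cross-validation."""

import numpy as np
import pytest

from pgxtl.baselines import WeightTable
from pgxtl.core import EffectPair, StrategyConfig, residualize, standardize_genotypes
from pgxtl.cv import (
    TuneGrid,
    _aligned_pre_vector,
    assign_folds,
    fit_transfer_model,
    nested_cv_prs,
    tune_hyperparameters,
)
from tests.conftest import make_cohort


class TestAssignFolds:
    def test_balanced_sizes(self):
        f = assign_folds(10, 5, seed=3)
        assert sorted(np.bincount(f.fold_labels)[1:]) == [2, 2, 2, 2, 2]

    def test_uneven_sizes_differ_by_one(self):
        f = assign_folds(7, 5, seed=3)
        sizes = sorted(np.bincount(f.fold_labels)[1:])
        assert sizes == [1, 1, 1, 2, 2]

    def test_deterministic_per_seed(self):
        a = assign_folds(40, 4, seed=11).fold_labels
        b = assign_folds(40, 4, seed=11).fold_labels
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, assign_folds(40, 4, seed=12).fold_labels)

    def test_stratification_preserves_arm_proportions(self, rng):
        t = np.array([0] * 60 + [1] * 20)
        f = assign_folds(80, 4, seed=5, stratify=t)
        for k in range(1, 5):
            assert (t[f.fold_labels == k] == 1).sum() == 5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(3, 5, seed=0)


def _pre_weight_table(ids, weights):
    return WeightTable.from_arrays(ids, ["A"] * len(ids), ["G"] * len(ids), weights)


def _brute_force_best(cohort, beta_pre_vec, strategy, grid, seed):
    """Naive cell-by-cell re-enumeration of the tuning grid (oracle)."""
    active = np.flatnonzero(beta_pre_vec)
    if active.size == 0:
        active = np.arange(len(beta_pre_vec))
    m = len(active)
    etas = [e / m for e in grid.eta_multipliers]
    folds = assign_folds(cohort.n_samples, 4, seed, stratify=cohort.treatment)
    dosages = cohort.genotypes.subset_variants(active).dosages
    pre = beta_pre_vec[active]
    gt_only = strategy.update_mode == "gt_only"
    scores = np.zeros((len(etas), len(grid.lambdas), grid.n_iter))
    dead = np.zeros((len(etas), len(grid.lambdas), grid.n_iter), dtype=bool)
    for f in range(1, 5):
        val = folds.fold_labels == f
        tr = ~val
        z_tr, stats = standardize_genotypes(dosages[tr])
        z_val, _ = standardize_genotypes(dosages[val], stats)
        y_tr, _, apply = residualize(cohort.phenotype[tr], None, cohort.treatment[tr],
                                     return_model=True)
        y_val = apply(cohort.phenotype[val], None, cohort.treatment[val])
        x = np.hstack([z_tr, z_tr * cohort.treatment[tr][:, None]])
        tv = cohort.treatment[val]
        for i, eta in enumerate(etas):
            for j, lam in enumerate(grid.lambdas):
                b = np.concatenate([pre, np.zeros(m) if strategy.gt_init == "zero" else pre])
                for r in range(grid.n_iter):
                    with np.errstate(over="ignore", invalid="ignore"):
                        new = (1 - lam) * b + eta * (x.T @ (y_tr - x @ b))
                    if gt_only:
                        new[:m] = b[:m]
                    if not np.isfinite(new).all() or np.abs(new).max() > 1e8:
                        dead[i, j, r:] = True  # same guard as the optimizer
                        break
                    b = new
                    pg = z_val @ b[:m]
                    pgt = z_val @ b[m:]
                    full = np.column_stack([np.ones(val.sum()), pg, pgt * tv])
                    c, *_ = np.linalg.lstsq(full, y_val, rcond=None)
                    sse_full = np.sum((y_val - full @ c) ** 2)
                    sst = np.sum((y_val - y_val.mean()) ** 2)
                    if strategy.tuning_criterion == "overall_r2":
                        scores[i, j, r] += 1 - sse_full / sst
                    else:
                        red = np.column_stack([np.ones(val.sum()), pg])
                        cr, *_ = np.linalg.lstsq(red, y_val, rcond=None)
                        sse_red = np.sum((y_val - red @ cr) ** 2)
                        scores[i, j, r] += (sse_red - sse_full) / sse_red
    scores /= 4
    scores[dead] = -np.inf
    best, best_score = None, -np.inf
    for j in sorted(range(len(grid.lambdas)), key=lambda j: -grid.lambdas[j]):
        for i in sorted(range(len(etas)), key=lambda i: etas[i]):
            for r in range(grid.n_iter):
                if np.isfinite(scores[i, j, r]) and scores[i, j, r] > best_score:
                    best_score = scores[i, j, r]
                    best = (etas[i], grid.lambdas[j], r + 1)
    return best, scores


class TestTuning:
    @pytest.mark.parametrize("name", ["M1", "M3", "M5"])
    def test_grid_selection_matches_brute_force(self, rng, name):
        cohort = make_cohort(rng, 200, 50)
        beta_pre = rng.normal(size=50) * (rng.random(50) < 0.6)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, beta_pre)
        strategy = StrategyConfig.from_name(name)
        grid = TuneGrid(n_iter=15)
        result = tune_hyperparameters(cohort, weights, strategy, grid, seed=9)
        pre_vec = _aligned_pre_vector(cohort.genotypes, weights)
        (eta, lam, r), scores = _brute_force_best(cohort, pre_vec, strategy, grid, 9)
        assert result.best_eta == pytest.approx(eta)
        assert result.best_lambda == lam
        assert result.best_r == r
        got = result.score_table.set_index(["eta", "lambda", "r"])["score"]
        m_act = np.flatnonzero(pre_vec).size
        for i, em in enumerate(grid.eta_multipliers):
            for j, lm in enumerate(grid.lambdas):
                for rr in range(grid.n_iter):
                    assert got[(em / m_act, lm, rr + 1)] == pytest.approx(
                        scores[i, j, rr], abs=1e-9)

    def test_single_cell_grid_returned_verbatim(self, rng):
        cohort = make_cohort(rng, 80, 10)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, rng.normal(size=10))
        grid = TuneGrid(eta_multipliers=(5.0,), lambdas=(0.5,), n_iter=1)
        result = tune_hyperparameters(cohort, weights, StrategyConfig.from_name("M1"),
                                      grid, seed=2)
        assert result.best_eta == pytest.approx(0.5)
        assert result.best_lambda == 0.5
        assert result.best_r == 1

    def test_default_grid_has_360_cells(self, rng):
        cohort = make_cohort(rng, 100, 8)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, rng.normal(size=8))
        result = tune_hyperparameters(cohort, weights, StrategyConfig.from_name("M1"),
                                      TuneGrid(), seed=2)
        assert len(result.score_table) == 4 * 3 * 30

    def test_gt_only_criteria_rank_identically(self, rng):
        # with beta_G fixed, overall and conditional R^2 order cells the same way
        cohort = make_cohort(rng, 150, 12)
        beta_pre = rng.normal(size=12)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, beta_pre)
        grid = TuneGrid(n_iter=10)
        m5 = tune_hyperparameters(cohort, weights, StrategyConfig.from_name("M5"),
                                  grid, seed=4)
        pre_vec = _aligned_pre_vector(cohort.genotypes, weights)
        # oracle under the conditional criterion with the gt_only update
        class _Cond:
            update_mode = "gt_only"
            gt_init = "zero"
            tuning_criterion = "conditional_r2"

        (eta_c, lam_c, r_c), scores_c = _brute_force_best(cohort, pre_vec, _Cond(), grid, 4)
        overall = m5.score_table.sort_values(["eta", "lambda", "r"])["score"].to_numpy()
        cond = scores_c.reshape(-1)
        # compare rankings cell by cell (scores differ by the fixed PRS_G part)
        order_a = np.argsort(np.argsort(overall))
        order_b = np.argsort(np.argsort(cond))
        corr = np.corrcoef(order_a, order_b)[0, 1]
        assert corr > 0.99


class TestNestedCV:
    def test_every_sample_scored_once_and_deterministic(self, rng):
        cohort = make_cohort(rng, 120, 10)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, rng.normal(size=10))
        grid = TuneGrid(eta_multipliers=(10.0,), lambdas=(0.5,), n_iter=5)
        res = nested_cv_prs(cohort, weights, StrategyConfig.from_name("M1"),
                            grid, k_outer=4, seed=7)
        assert np.isfinite(res.prs_g).all() and np.isfinite(res.prs_gt).all()
        assert len(res.prs_g) == 120
        res2 = nested_cv_prs(cohort, weights, StrategyConfig.from_name("M1"),
                             grid, k_outer=4, seed=7)
        np.testing.assert_array_equal(res.prs_g, res2.prs_g)
        np.testing.assert_array_equal(res.prs_gt, res2.prs_gt)

    def test_m5_keeps_pretrained_prognostic_weights(self, rng):
        cohort = make_cohort(rng, 120, 10)
        beta_pre = rng.normal(size=10)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, beta_pre)
        grid = TuneGrid(eta_multipliers=(10.0,), lambdas=(0.0,), n_iter=5)
        res = nested_cv_prs(cohort, weights, StrategyConfig.from_name("M5"),
                            grid, k_outer=4, seed=7)
        for eff in res.fold_effects:
            np.testing.assert_array_equal(eff.beta_g, beta_pre)

    def test_heldout_phenotype_cannot_leak_into_weights(self, rng):
        cohort = make_cohort(rng, 120, 10)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, rng.normal(size=10))
        grid = TuneGrid(eta_multipliers=(10.0,), lambdas=(0.5,), n_iter=5)
        strat = StrategyConfig.from_name("M1")
        res = nested_cv_prs(cohort, weights, strat, grid, k_outer=4, seed=7)
        fold1 = res.fold_labels == 1
        y_perm = cohort.phenotype.copy()
        y_perm[fold1] = rng.permutation(y_perm[fold1])
        cohort_perm = type(cohort)(cohort.genotypes, cohort.treatment, y_perm, None)
        res_perm = nested_cv_prs(cohort_perm, weights, strat, grid, k_outer=4, seed=7)
        np.testing.assert_array_equal(res.fold_effects[0].beta_g,
                                      res_perm.fold_effects[0].beta_g)
        np.testing.assert_array_equal(res.fold_effects[0].beta_gt,
                                      res_perm.fold_effects[0].beta_gt)


class TestTransferFit:
    def test_zero_pre_weights_fall_back_to_all_variants(self, rng):
        cohort = make_cohort(rng, 100, 6)
        pre = EffectPair.from_prognostic(cohort.genotypes.variant_ids, np.zeros(6))
        grid = TuneGrid(eta_multipliers=(10.0,), lambdas=(0.0,), n_iter=5)
        fit = fit_transfer_model(cohort, pre, StrategyConfig.from_name("M1"), grid, seed=1)
        assert len(fit.effects) == 6

    def test_predict_uses_training_standardization(self, rng):
        cohort = make_cohort(rng, 100, 6)
        weights = _pre_weight_table(cohort.genotypes.variant_ids, rng.normal(size=6))
        grid = TuneGrid(eta_multipliers=(10.0,), lambdas=(0.5,), n_iter=5)
        fit = fit_transfer_model(cohort, weights, StrategyConfig.from_name("M1"),
                                 grid, seed=1)
        pg, pgt = fit.predict(cohort.genotypes)
        z, _ = standardize_genotypes(
            cohort.genotypes.subset_variants(
                np.arange(6)).mean_impute().dosages, fit.geno_stats)
        np.testing.assert_allclose(pg, z @ fit.effects.beta_g, rtol=1e-10)
        np.testing.assert_allclose(pgt, z @ fit.effects.beta_gt, rtol=1e-10)
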