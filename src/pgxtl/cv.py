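"""Nested cross-validation and hyperparameter tuning for the transfer fit.

Real-data workflow: the target cohort is split into ``k_outer`` (default 5)
folds; on each outer-training set an inner 4-fold cross-validation scores
every (learning rate, shrinkage, iteration) grid cell, the best cell is
refit on the full outer-training set, and out-of-fold prognostic/predictive
scores are emitted for the held-out fold.  Simulation workflow: tune and
refit on a training cohort once (:func:`fit_transfer_model`) and evaluate on
an independent test set.

The learning-rate grid is ``{1, 10, 50, 100} / m`` with ``m`` the number of
variants carrying a nonzero pre-trained weight, the shrinkage grid is
``{0, 0.5, 0.99}`` and the iteration cap is 30; the whole descent trace is
kept so the best iteration is selected without re-running.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pgxtl.baselines import WeightTable, harmonize_weights
from pgxtl.core import (
    DIVERGENCE_BOUND,
    EffectPair,
    GenotypeMatrix,
    PGxCohort,
    StandardizeStats,
    StrategyConfig,
    active_variant_index,
    initial_state,
    residualize,
    standardize_genotypes,
)

__all__ = [
    "FoldAssignment",
    "TuneGrid",
    "TuneResult",
    "TransferFit",
    "NestedCVResult",
    "assign_folds",
    "tune_hyperparameters",
    "fit_transfer_model",
    "nested_cv_prs",
]


@dataclass
class FoldAssignment:
    """Near-equal fold labels in ``1..k``, reproducible from ``seed``."""

    fold_labels: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_labels = np.asarray(self.fold_labels, dtype=int)
        sizes = np.bincount(self.fold_labels, minlength=self.k + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")


def assign_folds(
    n: int, k: int, seed: int, stratify: np.ndarray | None = None
) -> FoldAssignment:
    """Seeded partition of ``n`` samples into ``k`` near-equal folds.

    With ``stratify`` (e.g. the treatment arm), labels are dealt round-robin
    within each stratum so every fold preserves arm proportions while overall
    fold sizes still differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    counter = 0
    if stratify is None:
        strata = [np.arange(n)]
    else:
        stratify = np.asarray(stratify)
        strata = [np.flatnonzero(stratify == v) for v in np.unique(stratify)]
    fold_order = rng.permutation(k)  # so fold 1 is not systematically largest
    for idx in strata:
        shuffled = rng.permutation(idx)
        for i in shuffled:
            labels[i] = fold_order[counter % k] + 1
            counter += 1
    return FoldAssignment(labels, k, seed)


@dataclass(frozen=True)
class TuneGrid:
    """Hyperparameter grid: eta multipliers over m, shrinkage values, iteration cap."""

    eta_multipliers: tuple[float, ...] = (1.0, 10.0, 50.0, 100.0)
    lambdas: tuple[float, ...] = (0.0, 0.5, 0.99)
    n_iter: int = 30

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.eta_multipliers):
            raise ValueError("eta multipliers must be positive")
        if any(not 0 <= lam < 1 for lam in self.lambdas):
            raise ValueError("lambda values must lie in [0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")


@dataclass
class TuneResult:
    """Best grid cell and the full inner-CV score table."""

    best_eta: float
    best_lambda: float
    best_r: int
    score_table: pd.DataFrame  # columns: eta, lambda, r, score

    def __post_init__(self) -> None:
        best = self.score_table.loc[
            (self.score_table["eta"] == self.best_eta)
            & (self.score_table["lambda"] == self.best_lambda)
            & (self.score_table["r"] == self.best_r),
            "score",
        ]
        if len(best) != 1 or best.iloc[0] < self.score_table["score"].max() - 1e-12:
            raise ValueError("best cell must attain the maximum score")


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _aligned_pre_vector(
    genotypes: GenotypeMatrix, pre_weights: WeightTable | EffectPair
) -> np.ndarray:
    """Pre-trained prognostic weights in cohort variant order (zero if absent).

    Weight tables are allele-harmonized against the cohort panel first.
    """
    beta = np.zeros(genotypes.n_variants)
    if isinstance(pre_weights, WeightTable):
        harmonized, _ = harmonize_weights(pre_weights, genotypes)
        ids = harmonized.variant_ids
        values = harmonized.weights
    else:
        ids = pre_weights.variant_ids.astype(str)
        values = pre_weights.beta_g
    index = {v: i for i, v in enumerate(genotypes.variant_ids.astype(str))}
    for vid, w in zip(ids, values):
        i = index.get(str(vid))
        if i is not None:
            beta[i] = w
    return beta


def _grid_traces(
    x: np.ndarray,
    y: np.ndarray,
    b0: np.ndarray,
    etas: np.ndarray,
    lams: np.ndarray,
    n_iter: int,
    gt_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the descent for every (eta, lambda) cell at once.

    All cells share the residual/gradient matmuls, which makes the full grid
    barely more expensive than a single cell.  Returns traces of shape
    ``(n_cells, n_iter, 2M)`` (cells ordered eta-major) and a boolean
    ``diverged`` mask of shape ``(n_cells, n_iter)``; once a cell diverges it
    stays flagged and its coefficients are frozen at zero.
    """
    n_eta, n_lam = len(etas), len(lams)
    n_cells = n_eta * n_lam
    eta_c = np.repeat(etas, n_lam)
    lam_c = np.tile(lams, n_eta)
    m2 = len(b0)
    b = np.tile(b0[:, None], (1, n_cells))
    traces = np.empty((n_cells, n_iter, m2))
    diverged = np.zeros((n_cells, n_iter), dtype=bool)
    dead = np.zeros(n_cells, dtype=bool)
    half = m2 // 2
    with np.errstate(over="ignore", invalid="ignore"):
        for r in range(n_iter):
            resid = y[:, None] - x @ b
            grad = x.T @ resid
            b = (1.0 - lam_c)[None, :] * b + eta_c[None, :] * grad
            if gt_only:
                b[:half, :] = b0[:half, None]
            bad = ~np.isfinite(b).all(axis=0)
            with np.errstate(invalid="ignore"):
                bad |= np.nanmax(np.abs(np.where(np.isfinite(b), b, 0.0)), axis=0) > DIVERGENCE_BOUND
            dead |= bad
            if dead.any():
                b[:, dead] = 0.0
            diverged[dead, r:] = True
            traces[:, r, :] = b.T
    return traces, diverged


def _criterion_scores(
    yv: np.ndarray,
    tv: np.ndarray,
    prs_g: np.ndarray,
    prs_gt: np.ndarray,
    which: str,
) -> float:
    """Validation criterion for one grid cell at one iteration.

    ``overall_r2``: R^2 of ``Y' ~ PRS_G + PRS_GT x T``; ``conditional_r2``:
    partial R^2 of the interaction term given ``PRS_G``.
    """
    ones = np.ones_like(yv)
    inter = prs_gt * tv
    full = np.column_stack([ones, prs_g, inter])
    sst = float(((yv - yv.mean()) ** 2).sum())
    if sst == 0:
        return -np.inf
    coef, *_ = np.linalg.lstsq(full, yv, rcond=None)
    sse_full = float(np.sum((yv - full @ coef) ** 2))
    if which == "overall_r2":
        return 1.0 - sse_full / sst
    red = np.column_stack([ones, prs_g])
    coef_r, *_ = np.linalg.lstsq(red, yv, rcond=None)
    sse_red = float(np.sum((yv - red @ coef_r) ** 2))
    if sse_red == 0:
        return 0.0
    return (sse_red - sse_full) / sse_red


def _select_best(
    scores: np.ndarray, etas: np.ndarray, lams: np.ndarray
) -> tuple[int, int, int]:
    """Argmax over (eta, lambda, r) with ties toward larger lambda, smaller
    eta, then smaller r — preferring the most regularized, earliest-stopped
    model."""
    best = None
    best_score = -np.inf
    n_eta, n_lam, n_iter = scores.shape
    for j in sorted(range(n_lam), key=lambda j: -lams[j]):
        for i in sorted(range(n_eta), key=lambda i: etas[i]):
            for r in range(n_iter):
                s = scores[i, j, r]
                if np.isfinite(s) and s > best_score + 0.0:
                    best_score = s
                    best = (i, j, r)
    if best is None:
        raise RuntimeError("all hyperparameter grid cells diverged")
    return best


def _prepare_fit_arrays(
    cohort: PGxCohort, active: np.ndarray
) -> tuple[GenotypeMatrix, np.ndarray]:
    g = cohort.genotypes.subset_variants(active).mean_impute()
    return g, g.dosages


def tune_hyperparameters(
    train: PGxCohort,
    pre_weights: WeightTable | EffectPair,
    strategy: StrategyConfig,
    grid: TuneGrid | None = None,
    seed: int = 0,
    k_inner: int = 4,
) -> TuneResult:
    """Inner cross-validation over the full (eta, lambda, r) grid.

    For each inner fold the descent runs on 3/4 of the training data from the
    strategy's initial state; the strategy's criterion is computed on the
    held-out quarter at every iteration of every cell and averaged across
    folds.  Genotype standardization and covariate/treatment residualization
    are fit on the 3/4 portion and applied to the held-out quarter.
    """
    grid = grid or TuneGrid()
    beta_pre = _aligned_pre_vector(train.genotypes, pre_weights)
    active = active_variant_index(beta_pre)
    m_eff = len(active)
    etas = np.asarray(grid.eta_multipliers, dtype=float) / m_eff
    lams = np.asarray(grid.lambdas, dtype=float)
    g_act, dosages = _prepare_fit_arrays(train, active)
    pre = EffectPair.from_prognostic(g_act.variant_ids, beta_pre[active])
    b0 = initial_state(pre, strategy).stacked
    gt_only = strategy.update_mode == "gt_only"
    folds = assign_folds(train.n_samples, k_inner, seed, stratify=train.treatment)
    n_eta, n_lam = len(etas), len(lams)
    sums = np.zeros((n_eta * n_lam, grid.n_iter))
    dead_any = np.zeros((n_eta * n_lam, grid.n_iter), dtype=bool)
    for f in range(1, k_inner + 1):
        val = folds.fold_labels == f
        tr = ~val
        z_tr, stats = standardize_genotypes(dosages[tr])
        z_val, _ = standardize_genotypes(dosages[val], stats)
        cov = train.covariates
        y_tr, _, apply = residualize(
            train.phenotype[tr], None if cov is None else cov[tr], train.treatment[tr],
            return_model=True,
        )
        y_val = apply(
            train.phenotype[val], None if cov is None else cov[val], train.treatment[val]
        )
        x_tr = np.hstack([z_tr, z_tr * train.treatment[tr][:, None]])
        traces, diverged = _grid_traces(x_tr, y_tr, b0, etas, lams, grid.n_iter, gt_only)
        dead_any |= diverged
        m = m_eff
        flat_g = traces[:, :, :m].reshape(-1, m)
        flat_gt = traces[:, :, m:].reshape(-1, m)
        pg = z_val @ flat_g.T  # (n_val, n_cells * n_iter)
        pgt = z_val @ flat_gt.T
        tv = train.treatment[val]
        for c in range(n_eta * n_lam):
            for r in range(grid.n_iter):
                col = c * grid.n_iter + r
                if diverged[c, r]:
                    continue
                sums[c, r] += _criterion_scores(
                    y_val, tv, pg[:, col], pgt[:, col], strategy.tuning_criterion
                )
    scores = np.where(dead_any, -np.inf, sums / k_inner)
    scores3 = scores.reshape(n_eta, n_lam, grid.n_iter)
    i, j, r = _select_best(scores3, etas, lams)
    rows = []
    for ci in range(n_eta):
        for cj in range(n_lam):
            for cr in range(grid.n_iter):
                rows.append((etas[ci], lams[cj], cr + 1, scores3[ci, cj, cr]))
    table = pd.DataFrame(rows, columns=["eta", "lambda", "r", "score"])
    return TuneResult(float(etas[i]), float(lams[j]), int(r + 1), table)


@dataclass
class TransferFit:
    """A tuned and refit transfer model, ready to score new samples."""

    effects: EffectPair
    tune_result: TuneResult
    geno_stats: StandardizeStats
    strategy: StrategyConfig

    def predict(self, genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Prognostic/predictive PRS for new samples.

        New dosage columns are standardized with the fitting-set statistics.
        """
        index = {v: i for i, v in enumerate(genotypes.variant_ids.astype(str))}
        cols = []
        keep = []
        for i, vid in enumerate(self.effects.variant_ids.astype(str)):
            j = index.get(vid)
            if j is None:
                continue
            cols.append(j)
            keep.append(i)
        if not cols:
            raise ValueError("no fitted variants present in the genotype matrix")
        g = genotypes.subset_variants(np.asarray(cols)).mean_impute()
        stats = StandardizeStats(
            self.geno_stats.mean[keep], self.geno_stats.sd[keep],
            self.geno_stats.zero_variance[keep],
        )
        z, _ = standardize_genotypes(g, stats)
        return z @ self.effects.beta_g[keep], z @ self.effects.beta_gt[keep]


def fit_transfer_model(
    train: PGxCohort,
    pre_weights: WeightTable | EffectPair,
    strategy: StrategyConfig,
    grid: TuneGrid | None = None,
    seed: int = 0,
    k_inner: int = 4,
) -> TransferFit:
    """Tune on the training cohort (inner CV) and refit at the best cell.

    This is the simulation-mode entry point: evaluation then happens on an
    independent test cohort via :meth:`TransferFit.predict`.
    """
    grid = grid or TuneGrid()
    tune = tune_hyperparameters(train, pre_weights, strategy, grid, seed, k_inner)
    beta_pre = _aligned_pre_vector(train.genotypes, pre_weights)
    active = active_variant_index(beta_pre)
    g_act, dosages = _prepare_fit_arrays(train, active)
    z, stats = standardize_genotypes(dosages)
    y = residualize(train.phenotype, train.covariates, train.treatment)
    x = np.hstack([z, z * train.treatment[:, None]])
    pre = EffectPair.from_prognostic(g_act.variant_ids, beta_pre[active])
    b0 = initial_state(pre, strategy).stacked
    traces, diverged = _grid_traces(
        x, y, b0, np.array([tune.best_eta]), np.array([tune.best_lambda]),
        tune.best_r, strategy.update_mode == "gt_only",
    )
    if diverged[0, -1]:
        raise RuntimeError("descent diverged at the tuned hyperparameters on the refit")
    m = len(active)
    final = traces[0, tune.best_r - 1]
    effects = EffectPair(final[:m], final[m:], g_act.variant_ids)
    return TransferFit(effects, tune, stats, strategy)


@dataclass
class NestedCVResult:
    """Out-of-fold scores plus per-fold weights and tuning summaries."""

    prs_g: np.ndarray
    prs_gt: np.ndarray
    sample_ids: np.ndarray
    fold_labels: np.ndarray
    fold_effects: list[EffectPair] = field(default_factory=list)
    fold_tuning: list[TuneResult] = field(default_factory=list)


def _child_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def nested_cv_prs(
    cohort: PGxCohort,
    pre_weights: WeightTable | EffectPair,
    strategy: StrategyConfig,
    grid: TuneGrid | None = None,
    k_outer: int = 5,
    seed: int = 0,
    global_residualize: bool = False,
) -> NestedCVResult:
    """Nested cross-validation producing one out-of-fold PRS pair per sample.

    Each outer-training set is tuned by inner 4-fold CV, refit at the best
    cell, and scored on its held-out fold with fitting-set standardization
    statistics.  ``global_residualize`` removes covariate/treatment effects
    once on the full cohort before splitting (the one-shot variant) instead
    of the default per-fold adjustment.
    """
    grid = grid or TuneGrid()
    if global_residualize:
        y_adj = residualize(cohort.phenotype, cohort.covariates, cohort.treatment)
        cohort = PGxCohort(cohort.genotypes, cohort.treatment, y_adj, None)
    folds = assign_folds(cohort.n_samples, k_outer, seed, stratify=cohort.treatment)
    n = cohort.n_samples
    prs_g = np.full(n, np.nan)
    prs_gt = np.full(n, np.nan)
    fold_effects: list[EffectPair] = []
    fold_tuning: list[TuneResult] = []
    for f in range(1, k_outer + 1):
        test = folds.fold_labels == f
        train = cohort.subset(np.flatnonzero(~test))
        try:
            fit = fit_transfer_model(
                train, pre_weights, strategy, grid, seed=_child_seed(seed, f)
            )
        except Exception as exc:  # annotate with the fold for debuggability
            raise RuntimeError(f"outer fold {f} failed: {exc}") from exc
        g_test = cohort.genotypes.subset_samples(np.flatnonzero(test))
        pg, pgt = fit.predict(g_test)
        prs_g[test] = pg
        prs_gt[test] = pgt
        fold_effects.append(fit.effects)
        fold_tuning.append(fit.tune_result)
    return NestedCVResult(
        prs_g, prs_gt, cohort.genotypes.sample_ids, folds.fold_labels,
        fold_effects, fold_tuning,
    )
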