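"""Joint PGx model and the two-dimensional penalized gradient descent.

The model for a continuous drug response in a two-arm trial is

    Y = C delta + G beta_G + (G o T) beta_GT + eps,

where ``G`` is the (column-standardized) dosage matrix, ``T`` the 0/1
treatment indicator, ``beta_G`` the prognostic (genotype main) effects and
``beta_GT`` the predictive (genotype-by-treatment interaction) effects.
Writing ``X = [G, G o T]`` and ``b = [beta_G, beta_GT]``, the fit minimizes
the ridge loss ``||y - X b||^2 + lambda_raw b' b`` by gradient descent from a
transfer-learning start: ``beta_G`` is initialized at weights pre-trained on
disease GWAS summary statistics, ``beta_GT`` at zero or at the same weights.
The reparameterized update used throughout (and exposed to tuning) is

    b_(r+1) = (1 - lam) b_(r) + eta X' (y - X b_(r)),

with ``lam in [0, 1)`` so the shrinkage factor can never flip signs.  Six
strategy variants (M1-M6) differ in which block is updated, how ``beta_GT``
is initialized, and which criterion drives hyperparameter tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PGxCohort",
    "EffectPair",
    "StrategyConfig",
    "DescentSettings",
    "DescentTrace",
    "StandardizeStats",
    "DescentDivergenceError",
    "residualize",
    "standardize_genotypes",
    "penalized_loss",
    "descent_step",
    "run_descent",
    "compute_prs",
    "STRATEGIES",
]

#: coordinates whose absolute value exceeds this abort the descent
DIVERGENCE_BOUND = 1e8


class DescentDivergenceError(RuntimeError):
    """Raised when gradient descent produces non-finite or exploding weights."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(
            message
            or f"gradient descent diverged at iteration {iteration}: "
            "non-finite or exploding coefficients (try a smaller learning rate)"
        )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _as_str_array(values: Sequence[str], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x variants) with per-variant metadata.

    Dosages count copies of the declared effect allele, real-valued in
    ``[0, 2]``; ``NaN`` marks a missing call until :meth:`mean_impute`.
    ``chrom``/``pos`` are optional (1-based positions) and only needed for
    LD-aware operations such as clumping.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    variant_ids: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants matrix")
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids")
        self.variant_ids = _as_str_array(self.variant_ids, "variant_ids")
        self.effect_alleles = _as_str_array(self.effect_alleles, "effect_alleles")
        self.other_alleles = _as_str_array(self.other_alleles, "other_alleles")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        for name in ("variant_ids", "effect_alleles", "other_alleles"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} length does not match dosage columns")
        uniq, counts = np.unique(self.variant_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise ValueError(f"duplicate variant id: {dup}")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=int)
        if self.chrom is not None:
            self.chrom = _as_str_array(np.asarray(self.chrom, dtype=object), "chrom")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def mean_impute(self) -> "GenotypeMatrix":
        """Replace missing dosages with the per-variant mean (in place is avoided)."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return GenotypeMatrix(
            d, self.sample_ids, self.variant_ids, self.effect_alleles,
            self.other_alleles, self.chrom, self.pos,
        )

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sample_ids,
            self.variant_ids[index],
            self.effect_alleles[index],
            self.other_alleles[index],
            None if self.chrom is None else self.chrom[index],
            None if self.pos is None else self.pos[index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[index, :],
            self.sample_ids[index],
            self.variant_ids,
            self.effect_alleles,
            self.other_alleles,
            self.chrom,
            self.pos,
        )


@dataclass
class PGxCohort:
    """Individual-level two-arm PGx data: genotypes, treatment, response, covariates."""

    genotypes: GenotypeMatrix
    treatment: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n = self.genotypes.n_samples
        if len(self.treatment) != n or len(self.phenotype) != n:
            raise ValueError("treatment/phenotype length does not match genotypes")
        if not np.isin(self.treatment, (0.0, 1.0)).all():
            raise ValueError("treatment must be coded 0/1")
        if (self.treatment == 1).sum() < 2 or (self.treatment == 0).sum() < 2:
            raise ValueError("both treatment arms need at least 2 samples")
        if not np.isfinite(self.phenotype).all():
            raise ValueError("phenotype must be finite")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.size == 0:
                self.covariates = None
            else:
                if self.covariates.ndim == 1:
                    self.covariates = self.covariates[:, None]
                if self.covariates.shape[0] != n:
                    raise ValueError("covariate rows do not match cohort size")

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    def subset(self, index: np.ndarray) -> "PGxCohort":
        return PGxCohort(
            self.genotypes.subset_samples(index),
            self.treatment[index],
            self.phenotype[index],
            None if self.covariates is None else self.covariates[index, :],
        )


@dataclass
class EffectPair:
    """Aligned prognostic/predictive weight vectors on the standardized-dosage scale."""

    beta_g: np.ndarray
    beta_gt: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.beta_g = np.asarray(self.beta_g, dtype=float)
        self.beta_gt = np.asarray(self.beta_gt, dtype=float)
        self.variant_ids = _as_str_array(self.variant_ids, "variant_ids")
        if not (len(self.beta_g) == len(self.beta_gt) == len(self.variant_ids)):
            raise ValueError("beta_g, beta_gt and variant_ids must align")
        if not (np.isfinite(self.beta_g).all() and np.isfinite(self.beta_gt).all()):
            raise ValueError("effect sizes must be finite")

    @classmethod
    def from_prognostic(cls, variant_ids: Sequence[str], beta_g: np.ndarray) -> "EffectPair":
        beta_g = np.asarray(beta_g, dtype=float)
        return cls(beta_g, np.zeros_like(beta_g), np.asarray(variant_ids, dtype=object))

    @property
    def stacked(self) -> np.ndarray:
        """Concatenated ``[beta_G, beta_GT]`` coefficient vector."""
        return np.concatenate([self.beta_g, self.beta_gt])

    def __len__(self) -> int:
        return len(self.beta_g)


_TABLE1 = {
    # name: (update_mode, gt_init, tuning_criterion)
    "M1": ("both", "zero", "overall_r2"),
    "M2": ("both", "pre", "overall_r2"),
    "M3": ("both", "zero", "conditional_r2"),
    "M4": ("both", "pre", "conditional_r2"),
    "M5": ("gt_only", "zero", "overall_r2"),
    "M6": ("gt_only", "pre", "overall_r2"),
}


@dataclass(frozen=True)
class StrategyConfig:
    """One of the six fitting strategies (M1-M6).

    ``update_mode`` chooses whether both effect blocks or only ``beta_GT``
    are updated (M5/M6 keep ``beta_G`` fixed at the pre-trained weights);
    ``gt_init`` sets the predictive start (zero, or the pre-trained
    prognostic weights); ``tuning_criterion`` selects overall R^2 or the
    interaction partial R^2 for hyperparameter tuning.  With ``beta_G``
    fixed the two criteria rank hyperparameters identically, so M5/M6 are
    registered under overall R^2.
    """

    name: str
    update_mode: str
    gt_init: str
    tuning_criterion: str

    def __post_init__(self) -> None:
        if self.name not in _TABLE1:
            raise ValueError(f"unknown strategy {self.name!r}; expected M1..M6")
        if _TABLE1[self.name] != (self.update_mode, self.gt_init, self.tuning_criterion):
            raise ValueError(
                f"{self.name} must have (update_mode, gt_init, criterion) "
                f"= {_TABLE1[self.name]}"
            )

    @classmethod
    def from_name(cls, name: str) -> "StrategyConfig":
        name = name.upper()
        if name not in _TABLE1:
            raise ValueError(f"unknown strategy {name!r}; expected one of M1..M6")
        return cls(name, *_TABLE1[name])


STRATEGIES = {name: StrategyConfig.from_name(name) for name in _TABLE1}


@dataclass(frozen=True)
class DescentSettings:
    """Reparameterized learning rate ``eta``, shrinkage ``penalty`` in [0,1), iteration cap."""

    learning_rate: float
    penalty: float
    n_iter: int

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.penalty < 1:
            raise ValueError("penalty must lie in [0, 1) to prevent sign flipping")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")


@dataclass
class DescentTrace:
    """Coefficient state after each of ``n_iter`` descent iterations."""

    beta_g: np.ndarray  # (n_iter, M)
    beta_gt: np.ndarray  # (n_iter, M)
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.beta_g.shape != self.beta_gt.shape:
            raise ValueError("beta_g and beta_gt trace shapes differ")
        if self.beta_g.shape[1] != len(self.variant_ids):
            raise ValueError("trace width does not match variant_ids")

    def __len__(self) -> int:
        return self.beta_g.shape[0]

    def state(self, r: int) -> EffectPair:
        """Effect pair after iteration ``r`` (1-based, matching the tuning grid)."""
        if not 1 <= r <= len(self):
            raise IndexError(f"iteration {r} outside 1..{len(self)}")
        return EffectPair(self.beta_g[r - 1], self.beta_gt[r - 1], self.variant_ids)

    @property
    def states(self) -> Iterator[EffectPair]:
        for r in range(1, len(self) + 1):
            yield self.state(r)


@dataclass
class StandardizeStats:
    """Per-variant mean/sd used to standardize dosage columns."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.zero_variance is None:
            self.zero_variance = self.sd <= 0
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def residualize(
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    treatment: np.ndarray,
    return_model: bool = False,
):
    """OLS residuals of the response on intercept + covariates + treatment.

    Pre-adjusting the response absorbs the ``C delta`` (and treatment main
    effect) term so the descent iteration never has to refit it.  When
    ``return_model`` is true, also returns the fitted coefficient vector and
    a callable applying the same adjustment to new data (fold hygiene).
    """
    y = np.asarray(phenotype, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if y.ndim != 1 or len(y) != len(t):
        raise ValueError("phenotype and treatment lengths must agree")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype cannot be residualized")
    cols = [np.ones_like(y)]
    names = ["intercept"]
    if covariates is not None and np.asarray(covariates).size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != len(y):
            raise ValueError("covariate rows must match phenotype length")
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"covariate_{j}")
    cols.append(t)
    names.append("treatment")
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first column lying in the span of its predecessors
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(design[:, :j]):
                raise ValueError(
                    f"rank-deficient residualization design: column {names[j]!r} "
                    "is collinear with earlier columns"
                )
        raise ValueError("rank-deficient residualization design")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef

    if not return_model:
        return resid

    def apply(y_new: np.ndarray, covariates_new: np.ndarray | None, t_new: np.ndarray) -> np.ndarray:
        y_new = np.asarray(y_new, dtype=float)
        new_cols = [np.ones_like(y_new)]
        if covariates is not None and np.asarray(covariates).size:
            cov_new = np.asarray(covariates_new, dtype=float)
            if cov_new.ndim == 1:
                cov_new = cov_new[:, None]
            new_cols.append(cov_new)
        new_cols.append(np.asarray(t_new, dtype=float)[:, None] if np.ndim(t_new) == 1 else t_new)
        d = np.column_stack(new_cols)
        return y_new - d @ coef

    return resid, coef, apply


def standardize_genotypes(
    g: GenotypeMatrix | np.ndarray,
    reference_stats: StandardizeStats | None = None,
) -> tuple[np.ndarray, StandardizeStats]:
    """Center and scale dosage columns (sd with denominator n-1).

    The tuning grid shares a single learning rate and penalty across all
    ``2M`` coordinates, which is only meaningful when columns are on a
    common scale.  Fitting-set statistics are reused on held-out data via
    ``reference_stats``; zero-variance columns map to 0 and are flagged.
    """
    if isinstance(g, GenotypeMatrix):
        dosages = g.dosages
    else:
        dosages = np.asarray(g, dtype=float)
        if dosages.ndim == 1:
            dosages = dosages[:, None]
    if reference_stats is None:
        mean = dosages.mean(axis=0)
        sd = dosages.std(axis=0, ddof=1) if dosages.shape[0] > 1 else np.zeros(dosages.shape[1])
        stats = StandardizeStats(mean, sd)
    else:
        stats = reference_stats
        if len(stats.mean) != dosages.shape[1]:
            raise ValueError("reference statistics do not align with dosage columns")
    safe_sd = np.where(stats.zero_variance, 1.0, stats.sd)
    z = (dosages - stats.mean) / safe_sd
    z[:, stats.zero_variance] = 0.0
    return z, stats


def _stack_design(g_std: np.ndarray, treatment: np.ndarray) -> np.ndarray:
    """Design ``X = [G, G o T]`` from standardized dosages and the raw 0/1 arm."""
    t = np.asarray(treatment, dtype=float)[:, None]
    return np.hstack([g_std, g_std * t])


def penalized_loss(
    b: EffectPair | np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    penalty_raw: float,
) -> float:
    """Ridge loss ``||y - X b||^2 + penalty_raw * b'b`` (response pre-residualized)."""
    bv = b.stacked if isinstance(b, EffectPair) else np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (len(y), len(bv)):
        raise ValueError(
            f"design is {x.shape}, expected ({len(y)}, {len(bv)}) for y and b"
        )
    if penalty_raw < 0:
        raise ValueError("penalty_raw must be nonnegative")
    resid = y - x @ bv
    return float(resid @ resid + penalty_raw * (bv @ bv))


def _update(
    bv: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    eta: float,
    lam: float,
    gt_only: bool,
) -> np.ndarray:
    grad_part = x.T @ (y - x @ bv)
    new = (1.0 - lam) * bv + eta * grad_part
    if gt_only:
        m = len(bv) // 2
        new[:m] = bv[:m]
    return new


def descent_step(
    b: EffectPair,
    x: np.ndarray,
    y: np.ndarray,
    settings: DescentSettings,
    strategy: StrategyConfig,
) -> EffectPair:
    """One reparameterized update ``(1-lam) b + eta X'(y - X b)``.

    Under ``gt_only`` strategies the gradient is evaluated at the full
    current state but only the ``beta_GT`` block moves.
    """
    bv = b.stacked
    if x.shape[1] != len(bv):
        raise ValueError("design width must equal 2M")
    with np.errstate(over="ignore", invalid="ignore"):
        new = _update(bv, x, y, settings.learning_rate, settings.penalty,
                      strategy.update_mode == "gt_only")
    if not np.isfinite(new).all() or np.abs(new).max() > DIVERGENCE_BOUND:
        raise DescentDivergenceError(1)
    m = len(b)
    return EffectPair(new[:m], new[m:], b.variant_ids)


def _descent_trace_arrays(
    x: np.ndarray,
    y: np.ndarray,
    b0: np.ndarray,
    eta: float,
    lam: float,
    n_iter: int,
    gt_only: bool,
) -> np.ndarray:
    """Run ``n_iter`` updates from b0, returning the (n_iter, 2M) trace."""
    trace = np.empty((n_iter, len(b0)))
    bv = b0.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for r in range(n_iter):
            bv = _update(bv, x, y, eta, lam, gt_only)
            if not np.isfinite(bv).all() or np.abs(bv).max() > DIVERGENCE_BOUND:
                raise DescentDivergenceError(r + 1)
            trace[r] = bv
    return trace


def active_variant_index(pre_beta_g: np.ndarray) -> np.ndarray:
    """Indices of variants entering the descent.

    Sparse baselines zero out most weights; those variants are excluded,
    which also sets ``m`` in the learning-rate grid.  If every pre-weight is
    zero (cold start without transfer), all variants enter.
    """
    pre_beta_g = np.asarray(pre_beta_g, dtype=float)
    nz = np.flatnonzero(pre_beta_g != 0)
    if nz.size == 0:
        return np.arange(len(pre_beta_g))
    return nz


def initial_state(pre: EffectPair, strategy: StrategyConfig) -> EffectPair:
    """Transfer-learning start: ``beta_G = pre``, ``beta_GT`` = 0 or pre."""
    gt0 = np.zeros_like(pre.beta_g) if strategy.gt_init == "zero" else pre.beta_g.copy()
    return EffectPair(pre.beta_g.copy(), gt0, pre.variant_ids)


def run_descent(
    cohort: PGxCohort,
    pre_weights: EffectPair,
    settings: DescentSettings,
    strategy: StrategyConfig,
) -> DescentTrace:
    """Fit the joint model on a cohort, returning the whole iteration trace.

    Handles the full plumbing for a single fitting set: variant alignment
    with the pre-trained weights (inner join by id), restriction to the
    active set of nonzero pre-weights, mean imputation, in-set genotype
    standardization, residualization of the response on intercept +
    covariates + treatment, and ``n_iter`` descent updates.  The trace is
    returned in full so tuning can pick the best iteration without
    re-running.
    """
    keep = active_variant_index(pre_weights.beta_g)
    pre = EffectPair(
        pre_weights.beta_g[keep], pre_weights.beta_gt[keep], pre_weights.variant_ids[keep]
    )
    order = {v: i for i, v in enumerate(cohort.genotypes.variant_ids.astype(str))}
    g_idx, w_idx = [], []
    for i, vid in enumerate(pre.variant_ids.astype(str)):
        j = order.get(vid)
        if j is not None:
            g_idx.append(j)
            w_idx.append(i)
    if not g_idx:
        raise ValueError("no overlap between cohort variants and pre-trained weights")
    g = cohort.genotypes.subset_variants(np.asarray(g_idx)).mean_impute()
    pre = EffectPair(
        pre.beta_g[w_idx], pre.beta_gt[w_idx], pre.variant_ids[w_idx]
    )
    g_std, _ = standardize_genotypes(g)
    x = _stack_design(g_std, cohort.treatment)
    y = residualize(cohort.phenotype, cohort.covariates, cohort.treatment)
    b0 = initial_state(pre, strategy).stacked
    trace = _descent_trace_arrays(
        x, y, b0, settings.learning_rate, settings.penalty, settings.n_iter,
        strategy.update_mode == "gt_only",
    )
    m = len(pre)
    return DescentTrace(trace[:, :m], trace[:, m:], pre.variant_ids)


def compute_prs(
    g: GenotypeMatrix | np.ndarray,
    effects: EffectPair,
    variant_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Prognostic and predictive scores ``PRS_G = G beta_G``, ``PRS_GT = G beta_GT``.

    Variants are matched by id (order-free inner join); allele orientation is
    assumed already reconciled (see :func:`pgxtl.baselines.harmonize_weights`,
    which sign-flips swapped-allele weights — the equivalent, for centered
    dosage columns, of recoding a dosage as ``2 - dosage``).  ``g`` may be a
    plain (standardized) matrix with ``variant_ids`` supplied separately.
    """
    if isinstance(g, GenotypeMatrix):
        dosages = g.dosages
        g_ids = g.variant_ids.astype(str)
    else:
        if variant_ids is None:
            raise ValueError("variant_ids required when g is a plain matrix")
        dosages = np.asarray(g, dtype=float)
        g_ids = np.asarray(variant_ids, dtype=str)
    w = {v: i for i, v in enumerate(effects.variant_ids.astype(str))}
    cols, weights_g, weights_gt = [], [], []
    for j, vid in enumerate(g_ids):
        i = w.get(vid)
        if i is None:
            continue
        cols.append(j)
        weights_g.append(effects.beta_g[i])
        weights_gt.append(effects.beta_gt[i])
    if not cols:
        raise ValueError("no variants shared between genotypes and effect weights")
    sub = dosages[:, cols]
    return sub @ np.asarray(weights_g), sub @ np.asarray(weights_gt)
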