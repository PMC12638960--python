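"""Synthetic disease GWAS + two-arm PGx cohorts with a known architecture.

Generative model, mirroring the study conditions the package is benchmarked
under:

* Per-SNP effect triples ``(mu_j, beta_j, alpha_j)`` — disease, prognostic
  and predictive effects — follow a spike-and-slab: a SNP is causal with
  probability ``p_causal`` and its triple is then MVN(0, Sigma) with
  ``Sigma = h_T^2 / (m * p_causal) * Omega``, so total genetic variance is
  conserved across SNP counts.  ``Omega`` couples the three effects through
  ``rho_DT`` (disease vs. prognostic) and ``rho_E`` (prognostic vs.
  predictive), with corner entry ``rho_DT * rho_E``.  Optionally only a
  fraction of causal SNPs affects both phenotypes, the rest being
  disease-only (``beta = alpha = 0``) or drug-only (``mu = 0``).
* Disease summary statistics add estimation noise,
  ``mu_hat_j ~ N(mu_j, s_j^2)`` with two-sided normal p-values; the default
  standard error follows the GWAS recipe ``s_j = 1/sqrt(2 n_base f_j (1-f_j))``.
* Genotypes are LD-block-structured: a latent Gaussian with exchangeable (or
  AR-1) within-block correlation thresholded into Hardy-Weinberg dosages at
  a MAF drawn uniformly per variant.
* The drug response is ``Y = beta_T T + G beta + (G o T) (gamma alpha) + eps``
  with ``T ~ Bernoulli(0.5)``, standardized-scale genetic effects, and the
  noise variance set from the *realized* genetic variance so the sample
  heritability matches ``h_D^2`` exactly in expectation per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from pgxtl.baselines import LDReference, SummaryStats, WeightTable, clump_and_threshold, fit_sparse_sumstat_baseline
from pgxtl.core import EffectPair, GenotypeMatrix, PGxCohort, standardize_genotypes
from pgxtl.cv import TuneGrid, _child_seed, fit_transfer_model
from pgxtl.evaluation import PRSPair, evaluate_prs

__all__ = [
    "SimScenario",
    "OmegaMatrix",
    "EffectTriple",
    "build_omega",
    "simulate_effects",
    "simulate_genotypes",
    "simulate_sumstats",
    "simulate_phenotypes",
    "simulate_cohorts",
    "run_scenario",
]


@dataclass(frozen=True)
class OmegaMatrix:
    """3x3 effect-correlation matrix over (disease, prognostic, predictive)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("Omega must be 3x3")
        if not np.allclose(m, m.T):
            raise ValueError("Omega must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("Omega must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValueError("Omega must be positive semidefinite")
        object.__setattr__(self, "matrix", m)

    @property
    def rho_dt(self) -> float:
        return float(self.matrix[0, 1])

    @property
    def rho_e(self) -> float:
        return float(self.matrix[1, 2])


def build_omega(rho_dt: float, rho_e: float) -> OmegaMatrix:
    """Effect-correlation matrix with entries (rho_DT, rho_E, rho_DT*rho_E)."""
    for name, v in (("rho_dt", rho_dt), ("rho_e", rho_e)):
        if not 0 <= v < 1:
            raise ValueError(f"{name} must lie in [0, 1), got {v}")
    m = np.array([
        [1.0, rho_dt, rho_dt * rho_e],
        [rho_dt, 1.0, rho_e],
        [rho_dt * rho_e, rho_e, 1.0],
    ])
    return OmegaMatrix(m)


@dataclass(frozen=True)
class SimScenario:
    """All generative parameters of one simulation condition.

    Defaults are the benchmark study conditions: 2000 SNPs, 1% causal, base
    heritability 0.5, target (drug-response) heritability 0.3, effect
    correlations 0.5, predictive scale ``gamma = 1``, treatment main effect
    0.5, 4000 training + 1000 independent test samples, a 100k-sample
    disease GWAS, all causal SNPs shared between phenotypes, MAF uniform on
    [0.05, 0.5] and exchangeable 0.5-correlated LD blocks of 10 SNPs.
    """

    m: int = 2000
    p_causal: float = 0.01
    h_t2: float = 0.5
    h_d2: float = 0.3
    rho_dt: float = 0.5
    rho_e: float = 0.5
    gamma: float = 1.0
    beta_t: float = 0.5
    n_train: int = 4000
    n_test: int = 1000
    n_base: int = 100_000
    shared_fraction: float = 1.0
    disease_only_fraction: float = 0.0
    drug_only_fraction: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    block_rho: float = 0.5
    ld_structure: str = "exchangeable"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_causal <= 1:
            raise ValueError("p_causal must lie in (0, 1]")
        if not (0 < self.h_t2 < 1 and 0 < self.h_d2 < 1):
            raise ValueError("heritabilities must lie in (0, 1)")
        build_omega(self.rho_dt, self.rho_e)  # validates correlations + PSD
        total = self.shared_fraction + self.disease_only_fraction + self.drug_only_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("shared/disease-only/drug-only fractions must sum to 1")
        if self.m * self.p_causal < 1:
            raise ValueError("expected causal count m * p_causal must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ld_structure not in ("exchangeable", "ar1"):
            raise ValueError("ld_structure must be 'exchangeable' or 'ar1'")


@dataclass
class EffectTriple:
    """True per-SNP effects: disease (mu), prognostic (beta), predictive (alpha)."""

    mu: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    causal: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.mu)
        if not (len(self.beta) == len(self.alpha) == len(self.causal) == n):
            raise ValueError("effect vectors must align")


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (handles boundary-singular Omega)."""
    w, v = np.linalg.eigh(m)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_effects(scenario: SimScenario, rng: np.random.Generator | None = None) -> EffectTriple:
    """Draw spike-and-slab effect triples under the scenario's Omega.

    Causal SNPs are split into shared / disease-only / drug-only groups by
    the scenario fractions (group counts are floors of fraction x causal
    count for the two specific groups); disease-only SNPs draw ``mu`` from
    its marginal, drug-only SNPs draw ``(beta, alpha)`` from their bivariate
    marginal, so per-component variances are preserved.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    m = scenario.m
    causal = rng.random(m) < scenario.p_causal
    idx = np.flatnonzero(causal)
    mu = np.zeros(m)
    beta = np.zeros(m)
    alpha = np.zeros(m)
    if idx.size:
        var = scenario.h_t2 / (m * scenario.p_causal)
        omega = build_omega(scenario.rho_dt, scenario.rho_e).matrix
        n_dis = int(np.floor(scenario.disease_only_fraction * idx.size))
        n_drug = int(np.floor(scenario.drug_only_fraction * idx.size))
        perm = rng.permutation(idx)
        dis_idx = perm[:n_dis]
        drug_idx = perm[n_dis:n_dis + n_drug]
        shared_idx = perm[n_dis + n_drug:]
        if shared_idx.size:
            draws = rng.standard_normal((shared_idx.size, 3)) @ _psd_factor(omega).T
            draws *= np.sqrt(var)
            mu[shared_idx] = draws[:, 0]
            beta[shared_idx] = draws[:, 1]
            alpha[shared_idx] = draws[:, 2]
        if dis_idx.size:
            mu[dis_idx] = rng.normal(0.0, np.sqrt(var), dis_idx.size)
        if drug_idx.size:
            biv = np.array([[1.0, scenario.rho_e], [scenario.rho_e, 1.0]])
            draws = rng.standard_normal((drug_idx.size, 2)) @ _psd_factor(biv).T
            draws *= np.sqrt(var)
            beta[drug_idx] = draws[:, 0]
            alpha[drug_idx] = draws[:, 1]
    return EffectTriple(mu, beta, alpha, causal)


def _variant_metadata(m: int, ld_block_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic variant ids and positions; blocks are 1 Mb apart so a
    250 kb LD window recovers them."""
    ids = np.asarray([f"snp{j + 1:06d}" for j in range(m)], dtype=object)
    block = np.arange(m) // ld_block_size
    within = np.arange(m) % ld_block_size
    pos = block * 1_000_000 + within * 1000 + 1
    chrom = np.asarray(["1"] * m, dtype=object)
    return ids, pos, chrom


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 10,
    block_rho: float = 0.5,
    seed: int = 0,
    structure: str = "exchangeable",
) -> GenotypeMatrix:
    """LD-block genotypes: thresholded latent Gaussian at Hardy-Weinberg.

    Within a block the latent correlation is exchangeable (``block_rho``) or
    AR-1; blocks are independent.  Dosages take values {0, 1, 2} with
    probabilities ``(1-f)^2, 2f(1-f), f^2`` at the per-variant MAF ``f``.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_range[0], maf_range[1], m)
    z = np.empty((n, m))
    for start in range(0, m, ld_block_size):
        stop = min(start + ld_block_size, m)
        k = stop - start
        if structure == "exchangeable":
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, k))
            z[:, start:stop] = np.sqrt(block_rho) * shared + np.sqrt(1 - block_rho) * own
        else:  # ar1
            corr = block_rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            chol = np.linalg.cholesky(corr)
            z[:, start:stop] = rng.standard_normal((n, k)) @ chol.T
    q_lo = spstats.norm.ppf((1 - maf) ** 2)
    q_hi = spstats.norm.ppf((1 - maf) ** 2 + 2 * maf * (1 - maf))
    dosages = np.where(z <= q_lo, 0.0, np.where(z <= q_hi, 1.0, 2.0))
    ids, pos, chrom = _variant_metadata(m, ld_block_size)
    return GenotypeMatrix(
        dosages,
        np.asarray([f"sample{i + 1:06d}" for i in range(n)], dtype=object),
        ids,
        np.asarray(["A"] * m, dtype=object),
        np.asarray(["G"] * m, dtype=object),
        chrom,
        pos,
    )


def simulate_sumstats(
    effects: EffectTriple,
    variants: GenotypeMatrix,
    se: np.ndarray | None = None,
    n_base: int = 100_000,
    freqs: np.ndarray | None = None,
    seed: int = 0,
) -> SummaryStats:
    """Noisy disease GWAS marginals: ``mu_hat_j ~ N(mu_j, s_j^2)``.

    Two-sided normal p-values ``p_j = 2 (1 - Phi(|mu_hat_j / s_j|))``.  When
    no SE vector is supplied it follows the allele-count recipe
    ``1 / sqrt(2 n_base f (1-f))`` at the (empirical, unless given)
    effect-allele frequency.
    """
    rng = np.random.default_rng(seed)
    m = len(effects.mu)
    if variants.n_variants != m:
        raise ValueError("variant metadata does not match effect length")
    if se is None:
        if freqs is None:
            freqs = np.clip(np.nanmean(variants.dosages, axis=0) / 2.0, 0.01, 0.99)
        se = 1.0 / np.sqrt(2.0 * n_base * freqs * (1.0 - freqs))
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    mu_hat = rng.normal(effects.mu, se)
    pvals = 2.0 * spstats.norm.sf(np.abs(mu_hat / se))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame({
        "variant_id": variants.variant_ids.astype(str),
        "chr": (variants.chrom if variants.chrom is not None else ["1"] * m),
        "pos": (variants.pos if variants.pos is not None else np.arange(1, m + 1)),
        "effect_allele": variants.effect_alleles.astype(str),
        "other_allele": variants.other_alleles.astype(str),
        "beta": mu_hat,
        "se": se,
        "p": pvals,
        "freq": freqs if freqs is not None else np.nan,
        "n": n_base,
    })
    return SummaryStats(table)


def simulate_phenotypes(
    g: GenotypeMatrix,
    effects: EffectTriple,
    scenario: SimScenario,
    seed: int = 0,
) -> PGxCohort:
    """Two-arm drug response ``Y = beta_T T + G beta + (G o T)(gamma alpha) + eps``.

    Effects act on the standardized-dosage scale.  The noise variance is set
    from the realized genetic variance so the in-sample genetic variance
    fraction of ``Y - beta_T T`` equals ``h_D^2``.
    """
    rng = np.random.default_rng(seed)
    z, _ = standardize_genotypes(g.mean_impute())
    t = (rng.random(g.n_samples) < 0.5).astype(float)
    genetic = z @ effects.beta + (z * t[:, None]) @ (scenario.gamma * effects.alpha)
    var_g = float(np.var(genetic, ddof=1))
    if var_g == 0:
        raise ValueError("zero genetic variance: all prognostic/predictive effects are zero")
    sigma2 = var_g * (1.0 - scenario.h_d2) / scenario.h_d2
    y = scenario.beta_t * t + genetic + rng.normal(0.0, np.sqrt(sigma2), g.n_samples)
    return PGxCohort(g, t, y, None)


def simulate_cohorts(
    scenario: SimScenario, seed: int | None = None
) -> tuple[PGxCohort, PGxCohort, EffectTriple, SummaryStats]:
    """One full draw: shared effects, train+test cohorts, disease sumstats.

    Train and test genotypes come from a single panel draw (shared MAFs and
    LD), and the phenotype noise scale is set once on the combined sample.
    """
    seed = scenario.seed if seed is None else seed
    effects = simulate_effects(scenario, np.random.default_rng(_child_seed(seed, 1)))
    g_all = simulate_genotypes(
        scenario.n_train + scenario.n_test, scenario.m, scenario.maf_range,
        scenario.ld_block_size, scenario.block_rho, _child_seed(seed, 2),
        scenario.ld_structure,
    )
    cohort = simulate_phenotypes(g_all, effects, scenario, _child_seed(seed, 3))
    sumstats = simulate_sumstats(
        effects, g_all, n_base=scenario.n_base, seed=_child_seed(seed, 4)
    )
    train = cohort.subset(np.arange(scenario.n_train))
    test = cohort.subset(np.arange(scenario.n_train, scenario.n_train + scenario.n_test))
    return train, test, effects, sumstats


def _baseline_weights(
    baseline: str,
    sumstats: SummaryStats,
    ld: LDReference,
    train: PGxCohort,
) -> WeightTable:
    if baseline == "lasso":
        return fit_sparse_sumstat_baseline(sumstats, ld)
    if baseline == "ct":
        return clump_and_threshold(sumstats, ld, tuning_data=train)
    raise ValueError("baseline must be 'lasso' or 'ct'")


def run_scenario(
    scenario: SimScenario,
    strategies: tuple[str, ...] = ("M1",),
    baseline: str = "lasso",
    n_repeats: int = 1,
    seed: int = 0,
    grid: TuneGrid | None = None,
    ld_panel_size: int = 500,
) -> pd.DataFrame:
    """Full benchmark pipeline, one row per (repeat, method).

    Per repeat: draw effects, genotypes and phenotypes; compute disease
    summary statistics; pre-train baseline weights (LD reference taken from
    a subsample of the training genotypes); tune and refit each transfer
    strategy on the training cohort; evaluate everything on the independent
    test cohort.  The disease-PRS comparator is evaluated by entering its
    prognostic score in both terms of the evaluation model.  Failures are
    recorded per repeat in the ``error`` column rather than aborting.
    """
    grid = grid or TuneGrid()
    rows = []
    for rep in range(n_repeats):
        rep_seed = _child_seed(seed, 100 + rep)
        try:
            train, test, effects, sumstats = simulate_cohorts(scenario, rep_seed)
            panel = train.genotypes.subset_samples(
                np.arange(min(ld_panel_size, train.n_samples))
            )
            ld = LDReference.from_genotypes(panel)
            weights = _baseline_weights(baseline, sumstats, ld, train)
        except Exception as exc:  # pragma: no cover - defensive batch guard
            rows.append({"repeat": rep, "method": f"dis_{baseline}", "error": str(exc)})
            continue
        n_active = int((weights.weights != 0).sum())
        # disease-PRS comparator: train-panel standardization, prognostic score
        try:
            z_tr, stats = standardize_genotypes(train.genotypes.mean_impute())
            z_te, _ = standardize_genotypes(test.genotypes.mean_impute().dosages, stats)
            eff = EffectPair.from_prognostic(weights.variant_ids, weights.weights)
            from pgxtl.core import compute_prs

            prs_dis, _ = compute_prs(z_te, eff, variant_ids=test.genotypes.variant_ids)
            report = evaluate_prs(
                test.phenotype, test.treatment, test.covariates,
                PRSPair(prs_dis, prs_dis),
            )
            rows.append({
                "repeat": rep, "method": f"dis_{baseline}", "n_active": n_active,
                "error": None, **report.to_dict(),
            })
        except Exception as exc:
            rows.append({"repeat": rep, "method": f"dis_{baseline}",
                         "n_active": n_active, "error": str(exc)})
        for name in strategies:
            from pgxtl.core import StrategyConfig

            try:
                fit = fit_transfer_model(
                    train, weights, StrategyConfig.from_name(name), grid,
                    seed=_child_seed(rep_seed, 200 + int(name[1:])),
                )
                pg, pgt = fit.predict(test.genotypes)
                report = evaluate_prs(
                    test.phenotype, test.treatment, test.covariates, PRSPair(pg, pgt)
                )
                rows.append({
                    "repeat": rep, "method": f"tl_{name}", "n_active": n_active,
                    "error": None, **report.to_dict(),
                })
            except Exception as exc:
                rows.append({"repeat": rep, "method": f"tl_{name}",
                             "n_active": n_active, "error": str(exc)})
    return pd.DataFrame(rows)
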