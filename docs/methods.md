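# Methods

## Problem and model

`pgxtl` predicts continuous drug response in a two-arm randomized trial from
genotypes, in the common situation where the trial is far too small to train
a polygenic score from scratch but a large GWAS of a genetically related
disease exists. The joint model for response `Y` in a cohort of `n`
individuals at `M` variants is

    Y = C δ + G β_G + (G ∘ T) β_GT + ε,

with `C` the non-genetic covariates, `G` the column-standardized dosage
matrix, `T ∈ {0,1}` the treatment arm, `β_G` the prognostic (genotype main)
effects and `β_GT` the predictive (genotype-by-treatment) effects. Writing
`X = [G, G ∘ T]` and `b = [β_G, β_GT]`, the fit minimizes the ridge loss
`‖y − X b‖² + λ_raw b′b`, where `y` is the response pre-residualized on
intercept + covariates + treatment (so `C δ` and the treatment main effect
vanish from the iteration).

Transfer learning enters through the start point and the step count: `β_G`
is initialized at per-SNP weights pre-trained on disease GWAS summary
statistics (`β_G^pre`), `β_GT` at zero or at the same weights, and gradient
descent runs for at most 30 iterations with the best iteration chosen by
cross-validation. The reparameterized update is

    b⁽ʳ⁺¹⁾ = (1 − λ) b⁽ʳ⁾ + η X′(y − X b⁽ʳ⁾),   λ ∈ [0, 1),

whose fixed point (when the iteration contracts) is the ridge solution
`(X′X + (λ/η) I)⁻¹ X′y`; the constraint `λ < 1` keeps the shrinkage factor
from flipping coefficient signs. In practice the grid's step sizes are often
too large for contraction and the iterates eventually grow; the method's
actual regularization is early stopping — the tuned iteration count `r`
almost always lies in the first few steps — with a divergence guard (below)
discarding iterates past the blow-up.

Six strategies share this machinery:

| strategy | updates            | β_GT start | tuning criterion         |
|----------|--------------------|------------|--------------------------|
| M1       | both blocks        | 0          | overall R²               |
| M2       | both blocks        | β_G^pre    | overall R²               |
| M3       | both blocks        | 0          | interaction partial R²   |
| M4       | both blocks        | β_G^pre    | interaction partial R²   |
| M5       | β_GT only          | 0          | overall R² (≡ partial)   |
| M6       | β_GT only          | β_G^pre    | overall R² (≡ partial)   |

Under M5/M6 the gradient is evaluated at the full current state but only the
`β_GT` block moves, so `β_G` stays bit-identical to the pre-trained weights;
with `β_G` fixed the two tuning criteria rank hyperparameters identically.

## Pre-trained weights

`β_G^pre` can be ingested from any upstream PRS method as a weight TSV
(harmonized to the target panel: inner join by variant id, sign flip on
swapped alleles, optional removal of strand-ambiguous A/T and C/G variants),
or computed in-repo:

* **Clumping + thresholding** — greedy LD pruning by ascending p-value
  (ties broken by variant id for determinism), retaining a variant unless
  its squared correlation with a retained variant within the window
  (default 250 kb) exceeds `r²` (default 0.1); then a p-value cutoff chosen
  on tuning data when available, else the most permissive cutoff.
* **Sparse summary-statistic lasso** — per LD block, cyclic
  soft-thresholding on `b′((1−s)R + s I)b − 2 b′r + l1 ‖b‖₁` over
  standardized marginal effects `r_j = z_j/√n_j`, with LD shrinkage
  `s = 0.5` and a 10-point geometric `l1` path; the path point is chosen by
  pseudo-validation (maximizing `b′r / √(b′Ab)`, the normalized agreement
  between the implied score and the marginal effects) unless
  individual-level tuning data is supplied. This is a self-contained sparse
  baseline in the penalized-summary-statistic family, not a re-implementation
  of any published estimator's exact objective or constants.

LD blocks come from a reference genotype panel, grouped by fixed windows
(default 250 kb) with between-block correlation set to zero and tiny negative
eigenvalues from sampling noise clipped to keep blocks PSD.

**Active set.** Only variants with a nonzero pre-trained weight enter the
descent, and `m` in the learning-rate grid `{1, 10, 50, 100}/m` is their
count. Sparse baselines thereby also perform feature selection for the
transfer fit. If every pre-weight is zero (a deliberate cold start without
transfer), all variants enter and `m = M` — an empty active set would be
degenerate.

## Tuning and cross-validation

* **Grid**: η ∈ {1, 10, 50, 100}/m, λ ∈ {0, 0.5, 0.99}, r ∈ 1..30
  (360 cells). The whole descent trace is stored so all `r` are scored in
  one run, and all (η, λ) cells share each iteration's matrix products, so
  the full grid costs barely more than one cell.
* **Inner loop**: 4-fold CV stratified by treatment arm; genotype
  standardization and covariate/treatment residualization are fit on the
  3/4 portion and applied to the held-out quarter; the criterion (overall R²
  of `Y′ ~ PRS_G + PRS_GT·T`, or the classic partial R² of the interaction
  term given `PRS_G`) is computed per fold and averaged.
* **Outer loop** (real-data mode): 5 folds, also arm-stratified; tuning and
  refit happen on each outer-training set, the held-out fold receives
  out-of-fold `PRS_G = G β̂_G` and `PRS_GT = G β̂_GT` using fitting-set
  standardization statistics. Simulation mode skips the outer loop: tune +
  refit once on the training cohort, evaluate on the independent test set.
* **Tie-breaks**: equal criterion values resolve toward larger λ, then
  smaller η, then smaller r — the most regularized, earliest-stopped model.
* **Divergence guard**: a grid cell whose coefficients become non-finite or
  exceed 1e8 in absolute value is scored −∞ from that iteration onward
  (earlier iterates remain valid candidates under best-`r` selection); the
  guard is per-cell, so one aggressive step size cannot fail a whole run.
  If every cell diverges the run errors out.

Treatment is kept as raw {0,1} when forming `G ∘ T` (no centering), matching
the generative model below. Missing dosages are mean-imputed per variant
within each fitting set before standardization.

## Evaluation

Scores are judged with `Y′ ~ PRS_G + PRS_GT × T`, where `Y′` is the response
residualized on intercept + covariates + treatment on the evaluation data
(no `PRS_GT` main effect is included). Reported: overall model R²; the R² of
the `PRS_G`-only model; the interaction partial R²
`(SSE_red − SSE_full)/SSE_red` (an R²-difference variant is available behind
`partial_mode="difference"`); and the two-sided t-test p-value on the
interaction coefficient. A numerically perfect reduced fit reports an
interaction partial R² of 0. Stratification summaries bin patients by a
score into quantiles (rank-based, ties broken by sample order) and contrast
arm means per bin with Welch 95% intervals, or split at top-percentile
cutoffs and report the differential treatment effect top-vs-rest.

When a disease PRS (prognostic weights only) is evaluated in this model, its
single score enters both terms, so the comparison measures how far a purely
prognostic score can mimic a predictive one.

## Synthetic data

The generator draws per-SNP effect triples (disease `μ_j`, prognostic
`β_j`, predictive `α_j`) from a spike-and-slab: causal with probability
`p_causal`, then MVN(0, Σ) with `Σ = h_T²/(m·p_causal) · Ω`, which conserves
total genetic variance across SNP counts. `Ω` has unit diagonal and
off-diagonals (ρ_DT, ρ_E, ρ_DT·ρ_E). Optionally only a fraction of causal
SNPs affects both phenotypes; disease-only SNPs draw `μ` from its marginal
and drug-only SNPs draw `(β, α)` from their ρ_E-correlated bivariate
marginal, preserving per-component variances. Summary statistics add
estimation noise `μ̂_j ~ N(μ_j, s_j²)` with two-sided normal p-values and the
default SE recipe `s_j = 1/√(2 n_base f_j (1−f_j))`. Genotypes are
latent-Gaussian LD blocks (exchangeable, or AR-1 via `ld_structure="ar1"`)
thresholded at Hardy–Weinberg proportions for a per-variant MAF drawn
uniformly. The response is

    Y = β_T T + G β + (G ∘ T)(γ α) + ε,   T ~ Bernoulli(0.5),

with effects on the standardized-dosage scale and the noise variance set
from the *realized* genetic variance so the in-sample genetic variance
fraction equals `h_D²` per dataset (removing MAF/LD-dependent drift).

Defaults define the benchmark conditions: m = 2000 SNPs, p_causal = 0.01,
h_T² = 0.5, h_D² = 0.3, ρ_DT = ρ_E = 0.5, γ = 1, β_T = 0.5,
n_train = 4000, n_test = 1000, n_base = 100 000, MAF ∈ [0.05, 0.5],
exchangeable 0.5-correlated blocks of 10 SNPs. h_T², β_T and the cohort
split are package choices of realistic values; they are configurable, and
the heritabilities/correlations/γ grids used in the tests mirror the
published sensitivity conditions.

What the generator does **not** emulate: real chromosome-scale LD (long-range
and irregular block structure), allele-frequency-dependent architectures,
population stratification, non-normal phenotypes, and genotyping missingness
patterns. Passing tests therefore demonstrate correctness of the machinery
and the expected qualitative behavior under a faithful but idealized
architecture — not real-data effect sizes. In particular, with synthetic
exchangeable LD the prognostic score retains more correlation with the
marginal component of the interaction term than real-LD analyses show, so
the prognostic partial R² declines more gently as γ grows.

## Numerical choices

* Genotype columns are standardized (sd with denominator n−1) within each
  fitting set; held-out data reuses fitting-set statistics; zero-variance
  columns map to 0 and are flagged. The shared η and single λ across 2M
  coordinates presuppose comparable column scales.
* The block lasso declares convergence at a max coordinate change < 1e−6
  and errors (naming the block) after 1000 sweeps.
* Fold assignment deals shuffled samples round-robin within arm strata from
  a seeded generator; all pipeline randomness derives from integer seeds via
  `SeedSequence`, and repeated runs are bit-identical per seed.
* TSV floats are written at 10 significant digits; PLINK dosages count
  allele 1 of the bim file; coordinates are 1-based.

## Scope and limitations

Continuous endpoints and an L2 penalty only (binary/survival outcomes and
L1/coordinate-descent variants are out of scope); a single λ shared by both
effect blocks; no annotation-informed SNP selection. The nested-CV p-values
are not corrected for the score-construction process itself; interaction
tests are evaluated on data never touched by fitting (independent test set
in simulation mode, out-of-fold scores in real-data mode). Even so, the
evaluation model carries no `PRS_GT` main effect, so when the prognostic
adjustment is incomplete (few causal SNPs, weakly informative pre-trained
weights) the T-averaged component of `PRS_GT × T` can correlate with
unexplained prognostic signal in `Y′`, leaving the interaction test mildly
anti-conservative under the null (a rejection rate of roughly 0.07 at a
nominal 0.05 in the hardest small-architecture settings). Test-suite and
benchmark problem sizes (e.g. 2000 SNPs, 4000 training samples, 10–20
repeats) are scaled-down package choices that preserve the conditions'
structure while keeping runs short.
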