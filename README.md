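# pgxtl

Transfer-learning polygenic scores for drug-response prediction and patient
stratification in two-arm pharmacogenomic (PGx) trials.

## The problem

Randomized PGx trials are small — usually far too small to train a polygenic
score for drug response from scratch — while GWAS of the related disease
phenotype have hundreds of thousands of samples. A disease PRS transplanted
into the trial captures only prognostic (genotype main) effects and, by
construction, none of the predictive (genotype-by-treatment interaction)
effects that actually drive differential drug response. `pgxtl` bridges the
two: it takes per-SNP weights pre-trained on disease GWAS summary statistics
and fine-tunes *both* effect types on the individual-level trial data.

## The model

For response **Y**, covariates **C**, standardized dosages **G** and arm
indicator **T** ∈ {0,1}:

    Y = Cδ + G β_G + (G∘T) β_GT + ε

With X = [G, G∘T], b = [β_G, β_GT] and y the response residualized on
intercept + covariates + treatment, the fit minimizes ‖y − Xb‖² + λ_raw b′b
by penalized gradient descent from the transfer start β_G = β_G^pre
(pre-trained weights), β_GT = 0 or β_G^pre:

    b⁽ʳ⁺¹⁾ = (1 − λ) b⁽ʳ⁾ + η X′(y − X b⁽ʳ⁾),    λ ∈ [0, 1)

Hyperparameters (η ∈ {1,10,50,100}/m over the m variants with nonzero
pre-weights, λ ∈ {0, 0.5, 0.99}, iteration r ≤ 30) are tuned by inner 4-fold
cross-validation; real-data runs wrap this in an outer 5-fold loop that
yields out-of-fold scores PRS_G = G β̂_G and PRS_GT = G β̂_GT for every
individual. Six strategies (M1–M6) vary which block is updated, the β_GT
start, and whether tuning maximizes overall R² of
Y′ ~ PRS_G + PRS_GT×T or the partial R² of the interaction term.

The package also ships two self-contained baselines for pre-training
weights from summary statistics (clumping+thresholding and a sparse
summary-statistic lasso with pseudo-validation), an evaluation module
(R² decomposition, interaction test, quantile / top-percentile treatment
effect stratification), and a fully seeded synthetic-data generator
(spike-and-slab effect triples coupled across disease and drug response,
LD-block genotypes, noisy summary statistics, two-arm phenotypes).
See `docs/methods.md` for the complete account.

## Worked example

```python
from pgxtl.simdata import SimScenario, run_scenario

scenario = SimScenario(m=1000, n_train=2000, n_test=1000, p_causal=0.01,
                       h_d2=0.3, rho_dt=0.5, rho_e=0.5)
table = run_scenario(scenario, strategies=("M1", "M5"), baseline="lasso",
                     n_repeats=3, seed=42)
summary = table.groupby("method")[["overall_r2", "partial_r2_g",
                                   "partial_r2_gt", "interaction_p"]].mean()
print(summary.round(4))
```

```
           overall_r2  partial_r2_g  partial_r2_gt  interaction_p
method
dis_lasso      0.0456        0.0418         0.0038         0.3136
tl_M1          0.1154        0.1106         0.0053         0.0646
tl_M5          0.1068        0.0418         0.0680         0.0000
```

Each row averages three simulated trials (2000 training / 1000 independent
test samples, 1000 SNPs, 1% causal, drug-response heritability 0.3, effect
correlations 0.5). The disease-PRS baseline (`dis_lasso`) explains ~4.6% of
the residualized response and cannot detect the interaction (p ≈ 0.31).
Fine-tuning with strategy M1 more than doubles overall R² (0.115), mostly
through the prognostic term; strategy M5 — which freezes the pre-trained
prognostic weights and updates only the predictive block — converts the same
information into a strong interaction signal (interaction partial R² 0.068,
p < 1e-4), which is what matters for patient stratification.

## Command line

```bash
pgxtl simulate --scenario scen.yaml --seed 7 --out data/        # synthetic dataset
pgxtl baseline --sumstats data/sumstats.tsv \
               --ld-panel data/train_genotypes.tsv --method lasso \
               --out weights.tsv                                # pre-trained weights
pgxtl fit      --genotypes data/train_genotypes.tsv \
               --phenotype data/train_phenotype.tsv \
               --weights weights.tsv --strategy M1 --seed 5 \
               --out fit/                                       # nested-CV PRS
pgxtl evaluate --prs fit/prs.tsv \
               --phenotype data/train_phenotype.tsv --out eval/ # report + stratification
pgxtl scenario --scenario scen.yaml --strategies M1,M5 \
               --repeats 10 --seed 1 --out metrics.tsv          # batched benchmark
```

Genotypes are accepted as PLINK bed/bim/fam or a headered dosage TSV; all
outputs are headered TSV/JSON and byte-reproducible per seed.

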