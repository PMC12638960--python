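"""Pre-training of prognostic weights from disease GWAS summary statistics.

The transfer-learning fit starts from per-SNP weights ``beta_G_pre``
estimated on a large disease GWAS.  Weights can be ingested from an external
file (any upstream PRS method), or computed in-repo with one of two
self-contained baselines:

* clumping + thresholding (C+T): greedy LD pruning by ascending p-value
  followed by a p-value cutoff, optionally tuned on held-out data;
* a sparse summary-statistic lasso: per LD block, cyclic soft-thresholding
  on the shrunken correlation system, with an l1 path chosen by
  pseudo-validation when no tuning data is available.

Both consume a :class:`SummaryStats` table and an :class:`LDReference`
built from a reference genotype panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pgxtl.core import GenotypeMatrix, PGxCohort, compute_prs, residualize, standardize_genotypes

__all__ = [
    "SummaryStats",
    "WeightTable",
    "LDReference",
    "HarmonizationReport",
    "harmonize_weights",
    "clump_and_threshold",
    "fit_sparse_sumstat_baseline",
]

_SUMSTAT_COLUMNS = ["variant_id", "chr", "pos", "effect_allele", "other_allele", "beta", "se", "p"]
_WEIGHT_COLUMNS = ["variant_id", "effect_allele", "other_allele", "weight"]

#: complementary-strand ambiguous allele pairs
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryStats:
    """Per-variant disease GWAS marginal statistics.

    The table requires ``variant_id, chr, pos, effect_allele, other_allele,
    beta, se, p`` and may carry ``freq`` (effect-allele frequency) and ``n``
    (GWAS sample size).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        if t["variant_id"].duplicated().any():
            dup = t.loc[t["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant id in summary statistics: {dup}")
        if (t["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class WeightTable:
    """Pre-trained per-SNP prognostic weights (``beta_G_pre``)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        if t["variant_id"].duplicated().any():
            dup = t.loc[t["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant id in weight table: {dup}")
        if not np.isfinite(t["weight"].to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")
        self.table = t

    @classmethod
    def from_arrays(cls, variant_ids, effect_alleles, other_alleles, weights) -> "WeightTable":
        return cls(pd.DataFrame({
            "variant_id": np.asarray(variant_ids, dtype=str),
            "effect_allele": np.asarray(effect_alleles, dtype=str),
            "other_allele": np.asarray(other_alleles, dtype=str),
            "weight": np.asarray(weights, dtype=float),
        }))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["variant_id"].to_numpy(dtype=str)


@dataclass
class LDReference:
    """Block-diagonal LD (dosage correlation) from a reference genotype panel.

    ``blocks`` is a list of ``(variant index array, correlation matrix)``
    pairs over a shared ``variant_ids`` ordering; correlation between blocks
    is treated as zero.
    """

    variant_ids: np.ndarray
    pos: np.ndarray
    chrom: np.ndarray
    blocks: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=str)
        for idx, corr in self.blocks:
            if corr.shape[0] != corr.shape[1] or corr.shape[0] != len(idx):
                raise ValueError("LD block shape does not match its index")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
                raise ValueError("LD block diagonal must be 1")
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise ValueError("LD block must be symmetric")
            if np.linalg.eigvalsh(corr).min() < -1e-8:
                raise ValueError("LD block is not numerically PSD")

    @classmethod
    def from_genotypes(cls, g: GenotypeMatrix, window_kb: float = 250.0) -> "LDReference":
        """Form fixed-window LD blocks from a reference panel.

        Variants are grouped per chromosome into consecutive windows of
        ``window_kb`` starting at the first position; correlations are
        computed within blocks only.  Positions default to consecutive
        1-based indices when absent.
        """
        g = g.mean_impute()
        pos = g.pos if g.pos is not None else np.arange(1, g.n_variants + 1)
        chrom = g.chrom if g.chrom is not None else np.asarray(["1"] * g.n_variants, dtype=object)
        z, stats = standardize_genotypes(g)
        window = window_kb * 1000.0
        blocks: list[tuple[np.ndarray, np.ndarray]] = []
        order = np.lexsort((pos, chrom.astype(str)))
        current: list[int] = []
        start_pos = None
        start_chrom = None

        def flush():
            if not current:
                return
            idx = np.asarray(current)
            sub = z[:, idx]
            if sub.shape[0] > 1:
                corr = np.corrcoef(sub, rowvar=False)
                corr = np.atleast_2d(corr)
                corr[~np.isfinite(corr)] = 0.0
                np.fill_diagonal(corr, 1.0)
                corr = 0.5 * (corr + corr.T)
                w, v = np.linalg.eigh(corr)
                if w.min() < 0:  # clip tiny negative eigenvalues from sampling noise
                    corr = (v * np.clip(w, 0.0, None)) @ v.T
                    d = np.sqrt(np.clip(np.diag(corr), 1e-12, None))
                    corr = corr / np.outer(d, d)
                    np.fill_diagonal(corr, 1.0)
            else:
                corr = np.eye(len(idx))
            blocks.append((idx, corr))

        for j in order:
            c, p = str(chrom[j]), pos[j]
            if start_pos is None or c != start_chrom or p - start_pos > window:
                flush()
                current = [j]
                start_pos, start_chrom = p, c
            else:
                current.append(j)
        flush()
        return cls(g.variant_ids, np.asarray(pos), np.asarray(chrom, dtype=object), blocks)

    def squared_correlation(self) -> dict[tuple[int, int], float]:
        """Sparse map of within-block squared correlations (index pairs, i < j)."""
        out: dict[tuple[int, int], float] = {}
        for idx, corr in self.blocks:
            k = len(idx)
            for a in range(k):
                for b in range(a + 1, k):
                    i, j = int(idx[a]), int(idx[b])
                    key = (i, j) if i < j else (j, i)
                    out[key] = float(corr[a, b] ** 2)
        return out


@dataclass
class HarmonizationReport:
    """Bookkeeping from reconciling a weight table against a target panel."""

    n_kept: int
    n_flipped: int
    n_dropped: int


def harmonize_weights(
    weights: WeightTable,
    target_variants: pd.DataFrame | GenotypeMatrix,
    drop_palindromic: bool = False,
) -> tuple[WeightTable, HarmonizationReport]:
    """Align a weight table to a target variant panel.

    Inner join on ``variant_id``; a weight whose alleles are swapped relative
    to the target has its sign flipped; unreconcilable allele pairs are
    dropped; strand-ambiguous (A/T, C/G) variants are dropped when
    ``drop_palindromic``.  The result is ordered as the target panel and
    annotated with the target's allele orientation.
    """
    if isinstance(target_variants, GenotypeMatrix):
        target = pd.DataFrame({
            "variant_id": target_variants.variant_ids.astype(str),
            "effect_allele": target_variants.effect_alleles.astype(str),
            "other_allele": target_variants.other_alleles.astype(str),
        })
    else:
        target = target_variants[["variant_id", "effect_allele", "other_allele"]].copy()
        target["variant_id"] = target["variant_id"].astype(str)
    w = weights.table.set_index("variant_id")
    rows = []
    n_flipped = n_dropped = 0
    for _, trow in target.iterrows():
        vid = str(trow["variant_id"])
        if vid not in w.index:
            continue
        wrow = w.loc[vid]
        wa, wb = str(wrow["effect_allele"]), str(wrow["other_allele"])
        ta, tb = str(trow["effect_allele"]), str(trow["other_allele"])
        if drop_palindromic and (wa.upper(), wb.upper()) in _PALINDROMIC:
            n_dropped += 1
            continue
        if ta == "." or tb == ".":
            # target panel without allele annotation (e.g. dosage TSV):
            # assume the stated orientation
            weight = float(wrow["weight"])
            ta, tb = wa, wb
        elif (wa, wb) == (ta, tb):
            weight = float(wrow["weight"])
        elif (wa, wb) == (tb, ta):
            weight = -float(wrow["weight"])
            n_flipped += 1
        else:
            n_dropped += 1
            continue
        rows.append((vid, ta, tb, weight))
    if not rows:
        raise ValueError("no reconcilable variants shared with the target panel")
    out = pd.DataFrame(rows, columns=_WEIGHT_COLUMNS)
    return WeightTable(out), HarmonizationReport(len(out), n_flipped, n_dropped)


# ---------------------------------------------------------------------------
# clumping + thresholding
# ---------------------------------------------------------------------------


def _prognostic_r2(weights: WeightTable, tuning_data: PGxCohort) -> float:
    """R^2 of the residualized response on the prognostic PRS of ``weights``."""
    nz = weights.table[weights.table["weight"] != 0]
    if nz.empty:
        return 0.0
    g = tuning_data.genotypes.mean_impute()
    z, _ = standardize_genotypes(g)
    effects = _weight_effect_pair(WeightTable(nz))
    try:
        prs, _ = compute_prs(z, effects, variant_ids=g.variant_ids)
    except ValueError:
        return 0.0
    y = residualize(tuning_data.phenotype, tuning_data.covariates, tuning_data.treatment)
    if np.ptp(prs) == 0:
        return 0.0
    design = np.column_stack([np.ones_like(prs), prs])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0


def _weight_effect_pair(weights: WeightTable):
    from pgxtl.core import EffectPair

    return EffectPair.from_prognostic(weights.variant_ids, weights.weights)


def clump_and_threshold(
    stats: SummaryStats,
    ld: LDReference,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    p_thresholds: tuple[float, ...] = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0),
    tuning_data: PGxCohort | None = None,
) -> WeightTable:
    """Clumping + thresholding (C+T) weights from marginal GWAS effects.

    Greedy clumping visits variants by ascending p-value (ties broken by
    variant id) and retains a variant unless its squared correlation with an
    already retained variant within ``window_kb`` exceeds ``r2_threshold``.
    For each p-value cutoff, weights equal the marginal effect ``beta`` for
    retained variants passing the cutoff and zero otherwise.  With
    ``tuning_data``, the cutoff maximizing prognostic R^2 is returned;
    otherwise the most permissive cutoff.
    """
    if not p_thresholds:
        raise ValueError("p_thresholds must be nonempty")
    t = stats.table
    ld_index = {v: i for i, v in enumerate(ld.variant_ids)}
    r2 = ld.squared_correlation()
    order = t.sort_values(["p", "variant_id"], kind="stable").index
    retained: list[int] = []  # row indices in stats order
    retained_ld: list[int | None] = []
    window = window_kb * 1000.0
    pos = t["pos"].to_numpy()
    chrom = t["chr"].astype(str).to_numpy()
    for row in order:
        vid = str(t.at[row, "variant_id"])
        li = ld_index.get(vid)
        keep = True
        for prev, prev_li in zip(retained, retained_ld):
            if chrom[prev] != chrom[row] or abs(int(pos[prev]) - int(pos[row])) > window:
                continue
            if li is None or prev_li is None:
                continue
            key = (li, prev_li) if li < prev_li else (prev_li, li)
            if r2.get(key, 0.0) > r2_threshold:
                keep = False
                break
        if keep:
            retained.append(row)
            retained_ld.append(li)
    retained_mask = np.zeros(len(t), dtype=bool)
    retained_mask[np.asarray(retained, dtype=int)] = True

    def weights_for(cutoff: float) -> WeightTable:
        sel = retained_mask & (t["p"].to_numpy() <= cutoff)
        w = np.where(sel, t["beta"].to_numpy(dtype=float), 0.0)
        return WeightTable.from_arrays(
            t["variant_id"].to_numpy(dtype=str),
            t["effect_allele"].to_numpy(dtype=str),
            t["other_allele"].to_numpy(dtype=str),
            w,
        )

    thresholds = sorted(p_thresholds)
    if tuning_data is None:
        best = weights_for(thresholds[-1])
    else:
        scored = [(_prognostic_r2(weights_for(c), tuning_data), c) for c in thresholds]
        best_cutoff = max(scored, key=lambda sc: (sc[0], sc[1]))[1]
        best = weights_for(best_cutoff)
    if not (best.weights != 0).any():
        import warnings

        warnings.warn("no variant passes any p-value threshold; all weights zero",
                      RuntimeWarning, stacklevel=2)
    return best


# ---------------------------------------------------------------------------
# sparse summary-statistic lasso
# ---------------------------------------------------------------------------


class LassoConvergenceError(RuntimeError):
    def __init__(self, block: int):
        self.block = block
        super().__init__(f"coordinate descent failed to converge in LD block {block}")


def _block_lasso(
    a: np.ndarray, r: np.ndarray, l1: float, block_index: int,
    tol: float = 1e-6, max_sweeps: int = 1000,
) -> np.ndarray:
    """Minimize ``b'Ab - 2 b'r + l1 ||b||_1`` by cyclic soft-thresholding.

    ``A`` has unit diagonal (shrunken correlation), so each coordinate update
    is ``b_j <- soft(r_j - sum_{k != j} A_jk b_k, l1 / 2)``.
    """
    k = len(r)
    b = np.zeros(k)
    thr = l1 / 2.0
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(k):
            rho = r[j] - (a[j] @ b - a[j, j] * b[j])
            new = np.sign(rho) * max(abs(rho) - thr, 0.0)
            delta = abs(new - b[j])
            if delta > max_delta:
                max_delta = delta
            b[j] = new
        if max_delta < tol:
            return b
    raise LassoConvergenceError(block_index)


def fit_sparse_sumstat_baseline(
    stats: SummaryStats,
    ld: LDReference,
    l1_grid: np.ndarray | None = None,
    shrink_s: float = 0.5,
    tuning_data: PGxCohort | None = None,
) -> WeightTable:
    """Sparse penalized weights from summary statistics and an LD reference.

    Per LD block, minimizes ``b'((1-s)R + sI)b - 2 b'r + l1 ||b||_1`` over
    standardized marginal effects ``r_j = z_j / sqrt(n_j)`` (with
    ``z = beta/se``), the familiar elastic-net-style system on shrunken LD.
    The l1 value is chosen by pseudo-validation — maximizing the normalized
    agreement ``b'r / sqrt(b'Ab)`` between the implied score and the
    marginal effects — unless individual-level ``tuning_data`` is supplied,
    in which case prognostic R^2 on that data decides.  Weights are on the
    standardized-genotype scale.
    """
    if not 0 <= shrink_s <= 1:
        raise ValueError("shrink_s must lie in [0, 1]")
    t = stats.table
    z = t["beta"].to_numpy(dtype=float) / t["se"].to_numpy(dtype=float)
    if "n" in t.columns and t["n"].notna().all():
        n = t["n"].to_numpy(dtype=float)
    else:
        n = np.full(len(t), max(float(len(t)), 1000.0))
    r_full = z / np.sqrt(n)
    # align stats rows to the LD reference ordering
    ld_index = {v: i for i, v in enumerate(ld.variant_ids)}
    stat_row_for_ld = np.full(len(ld.variant_ids), -1, dtype=int)
    for row, vid in enumerate(t["variant_id"].astype(str)):
        i = ld_index.get(vid)
        if i is not None:
            stat_row_for_ld[i] = row
    if (stat_row_for_ld < 0).all():
        raise ValueError("summary statistics share no variants with the LD reference")

    if l1_grid is None:
        rmax = float(np.abs(r_full).max())
        if rmax == 0:
            l1_grid = np.array([1.0])
        else:
            l1_grid = np.geomspace(2.0 * rmax, 0.02 * rmax, 10)
    l1_grid = np.asarray(sorted(l1_grid, reverse=True), dtype=float)

    solutions = []
    scores = []
    for l1 in l1_grid:
        beta = np.zeros(len(t))
        quad = 0.0
        lin = 0.0
        for bi, (idx, corr) in enumerate(ld.blocks):
            rows = stat_row_for_ld[idx]
            present = rows >= 0
            if not present.any():
                continue
            rows_p = rows[present]
            sub = corr[np.ix_(present, present)]
            a = (1.0 - shrink_s) * sub + shrink_s * np.eye(int(present.sum()))
            r = r_full[rows_p]
            b = _block_lasso(a, r, float(l1), bi)
            beta[rows_p] = b
            quad += float(b @ a @ b)
            lin += float(b @ r)
        solutions.append(beta)
        scores.append(lin / np.sqrt(quad) if quad > 0 else 0.0)

    def to_table(beta: np.ndarray) -> WeightTable:
        return WeightTable.from_arrays(
            t["variant_id"].to_numpy(dtype=str),
            t["effect_allele"].to_numpy(dtype=str),
            t["other_allele"].to_numpy(dtype=str),
            beta,
        )

    if tuning_data is not None:
        fits = [_prognostic_r2(to_table(b), tuning_data) for b in solutions]
        best = int(np.argmax(fits))
    else:
        best = int(np.argmax(scores))
    return to_table(solutions[best])
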