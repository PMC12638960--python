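"""Prediction-accuracy and patient-stratification metrics.

Performance of a prognostic/predictive score pair is judged with the linear
evaluation model

    Y' ~ PRS_G + PRS_GT x T,

where ``Y'`` is the response residualized on intercept + covariates +
treatment.  Reported quantities: overall model R^2, the R^2 of the
``PRS_G``-only model, the classic partial R^2 of the interaction term given
``PRS_G`` (``(SSE_red - SSE_full) / SSE_red``; an R^2-difference variant is
available), and the two-sided t-test p-value on the interaction coefficient.
Stratification summaries bin patients by a score and contrast arm means
(treatment effects) per bin or between a top-percentile group and the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from pgxtl.core import residualize

__all__ = [
    "PRSPair",
    "EvalReport",
    "StratificationResult",
    "evaluate_prs",
    "quantile_treatment_effects",
    "differential_te_by_cutoff",
]


@dataclass
class PRSPair:
    """Aligned prognostic and predictive scores for a set of samples."""

    prs_g: np.ndarray
    prs_gt: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.prs_g = np.asarray(self.prs_g, dtype=float)
        self.prs_gt = np.asarray(self.prs_gt, dtype=float)
        if self.prs_g.shape != self.prs_gt.shape:
            raise ValueError("prs_g and prs_gt must have equal length")
        if not (np.isfinite(self.prs_g).all() and np.isfinite(self.prs_gt).all()):
            raise ValueError("PRS values must be finite")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if len(self.sample_ids) != len(self.prs_g):
                raise ValueError("sample_ids length mismatch")


@dataclass
class EvalReport:
    """Evaluation-model summary for one score pair."""

    overall_r2: float
    partial_r2_g: float
    partial_r2_gt: float
    interaction_p: float
    interaction_coef: float

    def to_dict(self) -> dict[str, float]:
        return {
            "overall_r2": self.overall_r2,
            "partial_r2_g": self.partial_r2_g,
            "partial_r2_gt": self.partial_r2_gt,
            "interaction_p": self.interaction_p,
            "interaction_coef": self.interaction_coef,
        }


@dataclass
class StratificationResult:
    """Per-stratum treatment-effect summary table."""

    table: pd.DataFrame
    kind: str  # "quantile" or "cutoff"


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(np.sum((y - design @ coef) ** 2))
    return coef, sse


def evaluate_prs(
    y: np.ndarray,
    t: np.ndarray,
    covariates: np.ndarray | None,
    prs: PRSPair,
    partial_mode: str = "classic",
) -> EvalReport:
    """Fit the evaluation model and report R^2 decomposition + interaction test.

    ``partial_mode='classic'`` uses ``(SSE_red - SSE_full)/SSE_red`` for the
    interaction partial R^2; ``'difference'`` reports the plain R^2 gain of
    the interaction term.  All-zero score columns are tolerated (they simply
    contribute nothing); genuinely collinear nonzero regressors raise.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    yprime = residualize(y, covariates, t)
    if np.ptp(yprime) == 0:
        raise ValueError("residualized response is constant")
    n = len(yprime)
    ones = np.ones(n)
    inter = prs.prs_gt * t
    full = np.column_stack([ones, prs.prs_g, inter])
    nonzero_cols = [0] + [j for j in (1, 2) if np.ptp(full[:, j]) > 0 or full[:, j].any()]
    active = full[:, nonzero_cols]
    if np.linalg.matrix_rank(active) < active.shape[1]:
        # allow exactly-zero columns, reject true collinearity among the rest
        keep = [j for j in nonzero_cols if np.abs(full[:, j]).max() > 0]
        if np.linalg.matrix_rank(full[:, keep]) < len(keep):
            raise ValueError("collinear regressors in the evaluation model")
    sst = float(((yprime - yprime.mean()) ** 2).sum())
    coef_full, sse_full = _ols(full, yprime)
    overall_r2 = 1.0 - sse_full / sst
    red = np.column_stack([ones, prs.prs_g])
    _, sse_red = _ols(red, yprime)
    partial_r2_g = 1.0 - sse_red / sst
    if partial_mode == "classic":
        # a numerically perfect reduced fit leaves nothing for the interaction
        partial_r2_gt = 0.0 if sse_red <= 1e-12 * sst else (sse_red - sse_full) / sse_red
    elif partial_mode == "difference":
        partial_r2_gt = overall_r2 - partial_r2_g
    else:
        raise ValueError("partial_mode must be 'classic' or 'difference'")
    # two-sided t-test on the interaction coefficient
    if np.abs(inter).max() == 0:
        interaction_coef, interaction_p = 0.0, 1.0
    else:
        dof = n - full.shape[1]
        xtx = full.T @ full
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            xtx_inv = np.linalg.pinv(xtx)
        sigma2 = sse_full / dof if dof > 0 else np.nan
        se = float(np.sqrt(max(sigma2 * xtx_inv[2, 2], 0.0)))
        interaction_coef = float(coef_full[2])
        if se == 0 or not np.isfinite(se):
            interaction_p = 1.0
        else:
            tval = interaction_coef / se
            interaction_p = float(2.0 * spstats.t.sf(abs(tval), dof))
            interaction_p = min(max(interaction_p, np.finfo(float).tiny), 1.0)
    return EvalReport(
        float(overall_r2), float(partial_r2_g), float(partial_r2_gt),
        float(interaction_p), float(interaction_coef),
    )


def _rank_bins(score: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Quantile bins by stable rank (ties broken by sample order)."""
    order = np.argsort(score, kind="stable")
    return [np.sort(part) for part in np.array_split(order, n_bins)]


def _arm_te(y: np.ndarray, t: np.ndarray) -> tuple[float, float, int, int]:
    """Treatment effect (treated - control mean) and Welch 95% CI half-width."""
    y1, y0 = y[t == 1], y[t == 0]
    n1, n0 = len(y1), len(y0)
    te = float(y1.mean() - y0.mean())
    var = (y1.var(ddof=1) / n1 if n1 > 1 else 0.0) + (y0.var(ddof=1) / n0 if n0 > 1 else 0.0)
    return te, float(1.959964 * np.sqrt(var)), n1, n0


def quantile_treatment_effects(
    score: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    n_bins: int = 4,
) -> StratificationResult:
    """Per-quantile-bin treatment effects with Welch 95% confidence intervals."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    rows = []
    for b, idx in enumerate(_rank_bins(score, n_bins), start=1):
        tb = t[idx]
        if (tb == 1).sum() < 2 or (tb == 0).sum() < 2:
            raise ValueError(f"bin {b} has fewer than 2 samples in one arm")
        te, half, n1, n0 = _arm_te(y[idx], tb)
        rows.append((b, n1, n0, te, te - half, te + half))
    table = pd.DataFrame(
        rows, columns=["bin", "n_treated", "n_control", "te", "ci_low", "ci_high"]
    )
    return StratificationResult(table, "quantile")


def differential_te_by_cutoff(
    score: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    cutoffs: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90),
) -> StratificationResult:
    """Differential treatment effect, top-percentile group versus the rest.

    For each cutoff ``c`` the top ``c``% of samples by score (stable rank
    order) form one group; the differential TE is ``TE(top) - TE(rest)``.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(score)
    order = np.argsort(-score, kind="stable")  # descending; stable tie rule
    rows = []
    for c in cutoffs:
        k = int(round(n * c / 100.0))
        if k < 2 or n - k < 2:
            raise ValueError(f"cutoff {c}% leaves a degenerate group")
        top = order[:k]
        rest = order[k:]
        for name, idx in (("top", top), ("rest", rest)):
            tb = t[idx]
            if (tb == 1).sum() < 1 or (tb == 0).sum() < 1:
                raise ValueError(f"cutoff {c}%: {name} group lacks one arm")
        te_top, half_top, *_ = _arm_te(y[top], t[top])
        te_rest, half_rest, *_ = _arm_te(y[rest], t[rest])
        diff = te_top - te_rest
        half = float(np.hypot(half_top, half_rest))
        rows.append((c, len(top), len(rest), te_top, te_rest, diff, diff - half, diff + half))
    table = pd.DataFrame(
        rows,
        columns=[
            "cutoff_pct", "n_top", "n_rest", "te_top", "te_rest",
            "differential_te", "ci_low", "ci_high",
        ],
    )
    return StratificationResult(table, "cutoff")
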