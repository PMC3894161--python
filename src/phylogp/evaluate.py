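"""Scoring estimated site-specific rates against ground truth.

Two complementary views: a squared-error loss on log rates (log scale so
that differences among low, conservation-relevant rates are emphasized,
and sensitive to systematic bias), and ROC/AUC treating the slow sites as
positives ranked by estimated rate ascending (insensitive to monotone
bias, measuring pure discrimination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

from .simulate import RateField

__all__ = [
    "EvaluationReport",
    "MethodComparison",
    "log_rate_loss",
    "roc_curve",
    "average_roc",
    "top_k_conserved",
    "evaluate_estimates",
    "compare_methods",
]


def _rates(x) -> np.ndarray:
    return np.asarray(x.rates if isinstance(x, RateField) else x, dtype=float)


def log_rate_loss(true_rates, est_rates) -> float:
    """Mean squared difference of log substitution rates:
    (1/N) sum_i (log true_i - log est_i)^2."""
    t, e = _rates(true_rates), _rates(est_rates)
    if t.shape != e.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {e.shape}")
    if np.any(t <= 0) or np.any(e <= 0):
        raise ValueError("rates must be positive")
    d = np.log(t) - np.log(e)
    return float(d @ d / len(d))


def roc_curve(
    mask: np.ndarray, scores: np.ndarray, positives_are_low: bool = True
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC, slow sites as positives.

    ``mask`` flags the true positives (functional sites); ``scores`` are
    estimated rates, ranked ascending when ``positives_are_low`` (a low
    estimated rate predicts function).  Ties contribute half weight, so the
    AUC equals the normalized Mann–Whitney U statistic.
    """
    from sklearn.metrics import roc_curve as _sk_roc, auc as _sk_auc

    mask = np.asarray(mask, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if mask.all() or not mask.any():
        raise ValueError("ROC undefined: mask must contain both classes")
    s = -scores if positives_are_low else scores
    fpr, tpr, _ = _sk_roc(mask.astype(int), s)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def average_roc(
    curves: list[np.ndarray], grid: np.ndarray | None = None
) -> np.ndarray:
    """Vertical averaging: mean TPR at a common FPR grid across replicates."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    tprs = [np.interp(grid, c[:, 0], c[:, 1]) for c in curves]
    return np.column_stack([grid, np.mean(tprs, axis=0)])


def top_k_conserved(est_rates: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most slowly evolving sites, rate ascending; ties
    broken toward the smaller site index."""
    est_rates = np.asarray(est_rates, dtype=float)
    if not (0 < k <= len(est_rates)):
        raise ValueError(f"k must be in 1..{len(est_rates)}, got {k}")
    order = np.argsort(est_rates, kind="stable")
    return order[:k]


@dataclass
class EvaluationReport:
    """Scores of one estimate against one ground-truth field."""

    loss: float
    roc_points: np.ndarray
    auc: float
    top_k_sites: np.ndarray


def evaluate_estimates(
    field: RateField, est_rates: np.ndarray, k: int = 20
) -> EvaluationReport:
    """Loss, ROC/AUC and top-k conserved sites for one replicate."""
    pts, auc = roc_curve(field.functional_mask, np.asarray(est_rates))
    return EvaluationReport(
        loss=log_rate_loss(field.rates, est_rates),
        roc_points=pts,
        auc=auc,
        top_k_sites=top_k_conserved(est_rates, min(k, field.n_sites)),
    )


@dataclass
class MethodComparison:
    """Paired comparison of two estimators over replicates (A vs B)."""

    losses_a: np.ndarray
    losses_b: np.ndarray
    aucs_a: np.ndarray
    aucs_b: np.ndarray
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    mean_roc_a: np.ndarray
    mean_roc_b: np.ndarray

    @property
    def median_loss_a(self) -> float:
        return float(np.median(self.losses_a))

    @property
    def median_loss_b(self) -> float:
        return float(np.median(self.losses_b))


def compare_methods(
    fields: list[RateField],
    estimates_a: list[np.ndarray],
    estimates_b: list[np.ndarray],
) -> MethodComparison:
    """Score both methods on the same replicates: per-replicate losses and
    AUCs, a paired Wilcoxon signed-rank test on the losses, and vertically
    averaged ROC curves.

    If every loss pair is tied the Wilcoxon test is degenerate and is
    reported as (statistic=0, p=1).
    """
    if not (len(fields) == len(estimates_a) == len(estimates_b)):
        raise ValueError("replicate lists must have equal length")
    rep_a = [evaluate_estimates(f, e) for f, e in zip(fields, estimates_a)]
    rep_b = [evaluate_estimates(f, e) for f, e in zip(fields, estimates_b)]
    losses_a = np.array([r.loss for r in rep_a])
    losses_b = np.array([r.loss for r in rep_b])
    diffs = losses_a - losses_b
    if np.allclose(diffs, 0.0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(losses_a, losses_b)
    return MethodComparison(
        losses_a=losses_a,
        losses_b=losses_b,
        aucs_a=np.array([r.auc for r in rep_a]),
        aucs_b=np.array([r.auc for r in rep_b]),
        wilcoxon_statistic=float(stat),
        wilcoxon_pvalue=float(p),
        mean_roc_a=average_roc([r.roc_points for r in rep_a]),
        mean_roc_b=average_roc([r.roc_points for r in rep_b]),
    )
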