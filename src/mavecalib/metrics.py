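"""Discrimination and association metrics.

auROC is computed as the Mann–Whitney probability P(score_pos > score_neg)
with ties counted half — numerically identical to the trapezoidal area but
exact under ties. Tool comparison uses a class-stratified paired bootstrap
of the auROC difference. Diagnostic 2×2 metrics follow the conventions of
the common online diagnostic-test calculators: Clopper–Pearson exact
intervals for sensitivity/specificity/accuracy, and Mercaldo-style logit
intervals (propagating the sensitivity/specificity variances through the
predictive-value formula) for PPV/NPV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import mannwhitneyu, norm, pearsonr, rankdata
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

from .core import ValidationError

__all__ = [
    "RocCurve",
    "DiagnosticMetrics",
    "compute_auroc",
    "bootstrap_auroc_test",
    "pearson_r",
    "rank_sum_test",
    "diagnostic_metrics",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


def _as_bool_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise ValidationError("both classes must be present")
    return y


def _rank_auroc(scores: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(scores)  # midranks: ties count half
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_auroc(scores, labels, higher_is_positive: bool = True) -> RocCurve:
    """ROC curve and Mann–Whitney auROC; positives are the LoF proxy class."""
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if scores.shape != y.shape:
        raise ValidationError("scores and labels must be the same length")
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    oriented = scores if higher_is_positive else -scores
    fpr, tpr, thresholds = roc_curve(y.astype(int), oriented)
    return RocCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auroc=_rank_auroc(oriented, y)
    )


@dataclass
class AurocComparison:
    auroc_a: float
    auroc_b: float
    delta_auroc: float
    p_value: float
    n_boot: int


def bootstrap_auroc_test(
    scores_a,
    scores_b,
    labels,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> AurocComparison:
    """Paired, class-stratified bootstrap test of an auROC difference.

    Both score vectors must refer to the same variants. Each replicate
    resamples positives and negatives separately (preserving prevalence),
    recomputes both auROCs on the shared resample, and the two-sided p-value
    comes from the observed difference normalised by the bootstrap standard
    deviation of the difference.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _as_bool_labels(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValidationError("paired scores and labels must share a length")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; p-value will be unstable")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    auroc_a = _rank_auroc(a, y)
    auroc_b = _rank_auroc(b, y)
    delta_obs = auroc_a - auroc_b

    deltas = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            (
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            )
        )
        yy = y[idx]
        deltas[i] = _rank_auroc(a[idx], yy) - _rank_auroc(b[idx], yy)
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        p = 1.0 if delta_obs == 0.0 else 0.0
    else:
        p = float(2.0 * norm.sf(abs(delta_obs) / sd))
    return AurocComparison(
        auroc_a=auroc_a,
        auroc_b=auroc_b,
        delta_auroc=delta_obs,
        p_value=min(p, 1.0),
        n_boot=n_boot,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length inputs with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance input")
    return float(pearsonr(x, y).statistic)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum / Mann–Whitney test.

    Exact by full enumeration of label assignments when both samples have
    n ≤ 10 (ties handled via midranks); otherwise the normal approximation
    with tie correction. Returns (U statistic of ``x``, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate((x, y))
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 <= 10 and n2 <= 10:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for subset in combinations(range(n1 + n2), n1):
            u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetricWithCI:
    value: float  # percent
    ci: tuple[float, float]  # percent


@dataclass
class DiagnosticMetrics:
    """Percent-scale diagnostic test metrics from a 2×2 confusion table."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    accuracy: MetricWithCI


def _exact_ci(k: int, n: int, level: float) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return (100 * float(lo), 100 * float(hi))


def _logit_interval(point: float, var_logit: float, level: float) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2.0)
    logit = math.log(point / (1 - point))
    half = z * math.sqrt(var_logit)
    lo, hi = logit - half, logit + half
    inv = lambda t: 100.0 / (1.0 + math.exp(-t))
    return (inv(lo), inv(hi))


def diagnostic_metrics(
    tp: int,
    fn: int,
    fp: int,
    tn: int,
    level: float = 0.95,
    ppv_npv_method: str = "logit",
) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy with 95% CIs.

    ``ppv_npv_method`` is one of ``"logit"`` (Mercaldo-style, default),
    ``"exact"`` (Clopper–Pearson on the raw counts) or ``"wilson"``.
    """
    cells = dict(tp=tp, fn=fn, fp=fp, tn=tn)
    if any(v < 0 for v in cells.values()):
        raise ValidationError("cell counts must be non-negative")
    total = tp + fn + fp + tn
    if total == 0:
        raise ValidationError("empty table")
    for metric, margin in [
        ("sensitivity", tp + fn),
        ("specificity", fp + tn),
        ("PPV", tp + fp),
        ("NPV", fn + tn),
    ]:
        if margin == 0:
            raise ValidationError(f"{metric} undefined: empty margin")

    n1, n0 = tp + fn, fp + tn  # diseased / non-diseased totals
    sens = tp / n1
    spec = tn / n0
    ppv = tp / (tp + fp)
    npv = tn / (fn + tn)
    acc = (tp + tn) / total

    if ppv_npv_method == "logit" and min(tp, fn, fp, tn) > 0:
        # Mercaldo: delta-method variance of logit(PPV/NPV) through the
        # predictive-value formula at the observed prevalence.
        var_ppv = (1 - sens) / (n1 * sens) + spec / (n0 * (1 - spec))
        var_npv = sens / (n1 * (1 - sens)) + (1 - spec) / (n0 * spec)
        ppv_ci = _logit_interval(ppv, var_ppv, level)
        npv_ci = _logit_interval(npv, var_npv, level)
    elif ppv_npv_method == "wilson":
        lo, hi = proportion_confint(tp, tp + fp, alpha=1 - level, method="wilson")
        ppv_ci = (100 * float(lo), 100 * float(hi))
        lo, hi = proportion_confint(tn, fn + tn, alpha=1 - level, method="wilson")
        npv_ci = (100 * float(lo), 100 * float(hi))
    else:  # exact, and the zero-cell fallback for "logit"
        ppv_ci = _exact_ci(tp, tp + fp, level)
        npv_ci = _exact_ci(tn, fn + tn, level)

    return DiagnosticMetrics(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sensitivity=MetricWithCI(100 * sens, _exact_ci(tp, n1, level)),
        specificity=MetricWithCI(100 * spec, _exact_ci(tn, n0, level)),
        ppv=MetricWithCI(100 * ppv, ppv_ci),
        npv=MetricWithCI(100 * npv, npv_ci),
        accuracy=MetricWithCI(100 * acc, _exact_ci(tp + tn, total, level)),
    )
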