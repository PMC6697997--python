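"""Statistical layer: ROC with closest-to-corner threshold, rank-sum
tests, Pearson correlation, and stratified 11-fold cross-validation.

The operating point reported for each ROC curve is the point nearest the
upper-left corner (minimum Euclidean distance to (FPR, TPR) = (0, 1));
ties are broken toward higher specificity, then toward the smaller
threshold, so the choice is deterministic.  The Wilcoxon rank-sum test
uses exact enumeration (a dynamic program over tied average ranks) for
small samples and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "RocSummary",
    "WilcoxonResult",
    "CvPlan",
    "CvResult",
    "roc_analysis",
    "apply_threshold",
    "wilcoxon_rank_sum",
    "pearson_correlation",
    "make_cv_plan",
    "cross_validated_auc",
]


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocSummary:
    """ROC curve, AUC and the closest-to-corner operating point.

    The threshold is reported in feature units; the decision rule is
    ``score >= threshold => malignant`` when ``higher_is_malignant``,
    otherwise ``score <= threshold => malignant``.
    """

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    higher_is_malignant: bool
    fpr: np.ndarray
    tpr: np.ndarray


def roc_analysis(
    scores: np.ndarray,
    malignant: np.ndarray,
    orientation: str = "auto",
) -> RocSummary:
    """ROC analysis of one feature against the benign/malignant truth.

    ``orientation``: ``"higher"`` (high scores indicate malignancy),
    ``"lower"``, or ``"auto"`` which picks the direction giving
    AUC >= 0.5.  AUC is the trapezoidal area, equivalent to the
    Mann-Whitney pair count with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(malignant, dtype=bool)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for ROC analysis")

    if orientation not in ("auto", "higher", "lower"):
        raise ValueError("orientation must be 'auto', 'higher' or 'lower'")
    if orientation == "auto":
        fpr_h, tpr_h, _ = _roc_curve(y, scores, drop_intermediate=False)
        higher = _trapezoid_auc(fpr_h, tpr_h) >= 0.5
    else:
        higher = orientation == "higher"

    oriented = scores if higher else -scores
    fpr, tpr, thresholds = _roc_curve(y, oriented, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))

    finite = np.isfinite(thresholds)
    dist2 = (1.0 - tpr) ** 2 + fpr**2
    cand = np.flatnonzero(finite)
    if cand.size == 0:  # degenerate: single threshold value
        cand = np.arange(thresholds.size)
    # closest corner, then higher specificity (lower FPR), then smaller
    # threshold in original units
    reported = thresholds[cand] if higher else -thresholds[cand]
    order = np.lexsort((reported, fpr[cand], np.round(dist2[cand], 12)))
    best = cand[order[0]]

    thr = float(thresholds[best] if higher else -thresholds[best])
    summary = RocSummary(
        auc=area,
        threshold=thr,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        accuracy=float("nan"),
        higher_is_malignant=bool(higher),
        fpr=fpr,
        tpr=tpr,
    )
    pred = apply_threshold(scores, summary)
    acc = float((pred == y).mean())
    return RocSummary(
        auc=summary.auc,
        threshold=summary.threshold,
        sensitivity=summary.sensitivity,
        specificity=summary.specificity,
        accuracy=acc,
        higher_is_malignant=summary.higher_is_malignant,
        fpr=fpr,
        tpr=tpr,
    )


def apply_threshold(scores: np.ndarray, summary: RocSummary) -> np.ndarray:
    """Classify scores with a fitted operating point (True = malignant)."""
    scores = np.asarray(scores, dtype=float)
    if summary.higher_is_malignant:
        return scores >= summary.threshold
    return scores <= summary.threshold


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@dataclass(frozen=True)
class WilcoxonResult:
    """Rank-sum statistic (sum of group-a average ranks), z value and
    two-sided p."""

    statistic: float
    z: float
    pvalue: float
    method: str


def _exact_ranksum_p(ranks2: np.ndarray, n_a: int, w2: int) -> float:
    """Two-sided exact p for the rank-sum by DP enumeration.

    ``ranks2`` are pooled average ranks doubled to integers (ties give
    half-integer ranks); counts subsets of size ``n_a`` by doubled sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros((n_a + 1, total + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        counts[1:, r:] += counts[:-1, : total + 1 - r]
    dist = counts[n_a]
    denom = dist.sum()
    p_le = dist[: w2 + 1].sum() / denom
    p_ge = dist[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(
    group_a: np.ndarray, group_b: np.ndarray, method: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test with average ranks for ties.

    ``method``: ``"exact"`` enumerates the permutation distribution of
    the rank sum (exact even with ties), ``"normal"`` uses the
    tie-corrected normal approximation with continuity correction, and
    ``"auto"`` picks exact when the pooled sample has at most 12 values.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_a].sum())

    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = (n_a * (n - n_a) / 12.0) * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0

    if var <= 0:  # every pooled value identical: no separation possible
        return WilcoxonResult(statistic=w, z=0.0, pvalue=1.0, method="degenerate")

    z = (w - mu) / math.sqrt(var)
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    use_exact = method == "exact" or (method == "auto" and n <= 12)
    if use_exact:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        p = _exact_ranksum_p(ranks2, n_a, w2)
        return WilcoxonResult(statistic=w, z=z, pvalue=p, method="exact")
    zc = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(zc))))
    return WilcoxonResult(statistic=w, z=z, pvalue=p, method="normal")


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p (t transform)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CvPlan:
    """Fold assignment: ``fold_of[lesion_id]`` in 0..n_folds-1; each
    lesion serves as test exactly once and fold sizes differ by <= 1."""

    fold_of: dict[str, int]
    n_folds: int

    def test_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f != fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.fold_of.values():
            sizes[f] += 1
        return sizes


def _fold_totals(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    base, rem = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    big = rng.permutation(k)[:rem]
    sizes[big] += 1
    return sizes


def make_cv_plan(
    lesion_ids: list[str],
    labels: list[str],
    n_folds: int = 11,
    seed: int = 0,
    stratified: bool = True,
) -> CvPlan:
    """Random fold assignment, stratified by class by default.

    Combined fold sizes are fixed first (as equal as possible, e.g. six
    folds of 11 and five of 10 for 116 lesions in 11 folds), then each
    class's remainder is allocated to the largest folds so both the
    combined and the per-class balance hold.  Degrades gracefully when a
    class has fewer members than folds.
    """
    ids = list(lesion_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("lesion ids must be unique")
    n = len(ids)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds cohort size {n}")
    rng = np.random.default_rng(seed)
    totals = _fold_totals(n, n_folds, rng)

    fold_of: dict[str, int] = {}
    if not stratified:
        order = rng.permutation(n)
        bounds = np.cumsum(totals)
        starts = np.concatenate([[0], bounds[:-1]])
        for f, (lo, hi) in enumerate(zip(starts, bounds)):
            for idx in order[lo:hi]:
                fold_of[ids[idx]] = f
        return CvPlan(fold_of=fold_of, n_folds=n_folds)

    labels = list(labels)
    if len(labels) != n:
        raise ValueError("labels must match lesion_ids")
    remaining = totals.copy()
    classes = sorted(set(labels))
    # smallest class first so its remainder lands on the largest folds
    for cls in sorted(classes, key=lambda c: labels.count(c)):
        members = [i for i, l in zip(ids, labels) if l == cls]
        rng.shuffle(members)
        m = len(members)
        base, rem = divmod(m, n_folds)
        alloc = np.minimum(np.full(n_folds, base, dtype=int), remaining)
        # hand the remainder to folds with the most remaining room
        room = remaining - alloc
        order = np.lexsort((rng.random(n_folds), -room))
        for f in order[:rem]:
            if room[f] > 0:
                alloc[f] += 1
        # repair any shortfall caused by capacity clipping
        short = m - int(alloc.sum())
        while short > 0:
            room = remaining - alloc
            f = int(np.argmax(room))
            alloc[f] += 1
            short -= 1
        pos = 0
        for f in range(n_folds):
            for member in members[pos : pos + alloc[f]]:
                fold_of[member] = f
            pos += alloc[f]
        remaining = remaining - alloc
    return CvPlan(fold_of=fold_of, n_folds=n_folds)


@dataclass(frozen=True)
class CvResult:
    """Per-fold operating-point transfer and the fold-averaged metrics."""

    fold_summaries: list[RocSummary | None]
    mean_auc: float
    mean_sensitivity: float
    mean_specificity: float
    mean_accuracy: float
    skipped_folds: tuple[int, ...]


def cross_validated_auc(
    scores_by_id: dict[str, float],
    malignant_by_id: dict[str, bool],
    plan: CvPlan,
) -> CvResult:
    """K-fold evaluation of one feature: the ROC threshold is fitted on
    each training portion and applied to the held-out fold; fold metrics
    are averaged arithmetically.

    A test fold containing a single class contributes no test AUC and is
    skipped (with a warning) for the averaged operating-point metrics.
    """
    missing = set(plan.fold_of) - set(scores_by_id)
    if missing:
        raise ValueError(f"plan covers ids without scores: {sorted(missing)[:5]}")
    fold_summaries: list[RocSummary | None] = []
    sens, spec, accs, aucs = [], [], [], []
    skipped: list[int] = []
    for fold in range(plan.n_folds):
        train = plan.train_ids(fold)
        test = plan.test_ids(fold)
        y_train = np.array([malignant_by_id[i] for i in train])
        s_train = np.array([scores_by_id[i] for i in train])
        y_test = np.array([malignant_by_id[i] for i in test])
        s_test = np.array([scores_by_id[i] for i in test])
        fitted = roc_analysis(s_train, y_train)
        if y_test.all() or not y_test.any():
            warnings.warn(f"fold {fold}: single-class test portion, skipped")
            skipped.append(fold)
            fold_summaries.append(None)
            continue
        fpr_t, tpr_t, _ = _roc_curve(
            y_test, s_test if fitted.higher_is_malignant else -s_test,
            drop_intermediate=False,
        )
        pred = apply_threshold(s_test, fitted)
        tp = int((pred & y_test).sum())
        tn = int((~pred & ~y_test).sum())
        summary = RocSummary(
            auc=float(_trapezoid_auc(fpr_t, tpr_t)),
            threshold=fitted.threshold,
            sensitivity=tp / int(y_test.sum()),
            specificity=tn / int((~y_test).sum()),
            accuracy=(tp + tn) / y_test.size,
            higher_is_malignant=fitted.higher_is_malignant,
            fpr=fpr_t,
            tpr=tpr_t,
        )
        fold_summaries.append(summary)
        sens.append(summary.sensitivity)
        spec.append(summary.specificity)
        accs.append(summary.accuracy)
        aucs.append(summary.auc)
    if not accs:
        raise ValueError("every fold was skipped; cannot average")
    return CvResult(
        fold_summaries=fold_summaries,
        mean_auc=float(np.mean(aucs)),
        mean_sensitivity=float(np.mean(sens)),
        mean_specificity=float(np.mean(spec)),
        mean_accuracy=float(np.mean(accs)),
        skipped_folds=tuple(skipped),
    )
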