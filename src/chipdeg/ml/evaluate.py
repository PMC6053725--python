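"""Splits, cross-validation and metrics.

All random assignment is seeded; fold and split sizes follow round-half-up
with per-class largest-remainder allocation so that an 80/20 split of 2674
labeled genes yields exactly 2139 training and 535 testing genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chipdeg.ml.classify import POSITIVE_CLASS, train_classifier
from chipdeg.ml.selection import rank_features, select_top_fraction
from chipdeg.util import round_half_up

logger = logging.getLogger(__name__)


@dataclass
class TrainTestSplit:
    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    seed: int


def largest_remainder_allocation(
    class_counts: dict[str, int], total: int
) -> dict[str, int]:
    """Integer per-class quotas summing exactly to ``total``, proportional to
    class sizes, remainders resolved largest-first (ties by class name)."""
    n = sum(class_counts.values())
    quotas = {c: total * k / n for c, k in class_counts.items()}
    base = {c: min(math.floor(q), class_counts[c]) for c, q in quotas.items()}
    leftover = total - sum(base.values())
    order = sorted(
        class_counts,
        key=lambda c: (-(quotas[c] - math.floor(quotas[c])), c),
    )
    alloc = dict(base)
    i = 0
    while leftover > 0:
        c = order[i % len(order)]
        if alloc[c] < class_counts[c]:
            alloc[c] += 1
            leftover -= 1
        i += 1
    return alloc


def stratified_split(
    ids: Sequence[str],
    labels: Sequence[str],
    fraction: float = 0.8,
    seed: int = 0,
) -> TrainTestSplit:
    """Random stratified split with exact round-half-up training size.

    Classes with fewer than 2 members go entirely to training (with a
    warning); the remaining training quota is allocated per class by largest
    remainder so the total hits ``round_half_up(fraction * N)`` exactly.
    """
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels must have the same length")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes")
    n_train = round_half_up(fraction * len(ids))
    by_class: dict[str, list[str]] = {}
    for gid, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(gid)

    forced = {c: members for c, members in by_class.items() if len(members) < 2}
    for c in forced:
        logger.warning("class %r has < 2 members; all assigned to training", c)
    free = {c: members for c, members in by_class.items() if c not in forced}
    n_forced = sum(len(m) for m in forced.values())
    alloc = largest_remainder_allocation(
        {c: len(m) for c, m in free.items()}, max(0, n_train - n_forced)
    )

    rng = np.random.default_rng(seed)
    train: list[str] = [gid for members in forced.values() for gid in members]
    test: list[str] = []
    for c in sorted(free):
        members = sorted(free[c])
        perm = rng.permutation(len(members))
        k = alloc[c]
        train.extend(members[i] for i in perm[:k])
        test.extend(members[i] for i in perm[k:])
    return TrainTestSplit(
        train_ids=sorted(train), test_ids=sorted(test), fraction=fraction, seed=seed
    )


def stratified_folds(labels: Sequence[str], folds: int, seed: int = 0) -> np.ndarray:
    """Per-instance fold ids in ``0..folds-1``, class-stratified, seeded."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        assignment[idx] = (np.arange(len(idx)) + offset) % folds
        offset += len(idx)  # stagger classes so fold sizes balance
    return assignment


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Accuracy, precision, recall, F (positive-class and class-weighted) and
    MCC from a binary confusion table; undefined ratios are reported as 0
    with the offending metric listed under ``flags``."""
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion table")
    flags: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f_pos = ratio(2 * precision * recall, precision + recall, "f_measure")
    # negative class treated as positive for the weighted form
    precision_neg = ratio(tn, tn + fn, "precision_neg")
    recall_neg = ratio(tn, tn + fp, "recall_neg")
    f_neg = ratio(
        2 * precision_neg * recall_neg, precision_neg + recall_neg, "f_neg"
    )
    support_pos = tp + fn
    support_neg = tn + fp
    f_weighted = (
        (f_pos * support_pos + f_neg * support_neg) / total if total else 0.0
    )
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f_measure": f_pos,
        "f_weighted": f_weighted,
        "mcc": mcc,
        "flags": flags,
    }


def roc_auc(scores: Sequence[float], labels: Sequence) -> tuple[float, list[tuple[float, float]]]:
    """AUC (Mann-Whitney form, ties count 1/2) and the ROC point list.

    ``labels`` may be booleans or the up/down strings; both classes must be
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        pos = labels == POSITIVE_CLASS
    else:
        pos = labels
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if pos[order[j]]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return float(auc), points


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation results."""

    classifier: str
    folds: int
    seed: int
    fold_metrics: list[dict] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    auc: float = float("nan")
    selected_features: list[list[str]] = field(default_factory=list)


def cross_validate(
    classifier: str,
    X: pd.DataFrame,
    y: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    selector: Optional[str] = None,
    top_fraction: Optional[float] = None,
) -> CVReport:
    """Stratified k-fold cross-validation with in-fold feature selection.

    When ``selector`` is given, features are ranked on each training fold
    only and the top fraction kept — no information leaks from the held-out
    fold. Pooled metrics come from the summed confusion table; AUC from the
    pooled out-of-fold probabilities. Folds whose training part has a single
    class are skipped with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y)
    fold_ids = stratified_folds(y, folds, seed)
    report = CVReport(classifier=classifier, folds=folds, seed=seed)
    pooled_scores: list[float] = []
    pooled_labels: list[str] = []
    tp = fp = fn = tn = 0
    for k in range(folds):
        test_mask = fold_ids == k
        train_mask = ~test_mask
        if test_mask.sum() == 0:
            continue
        y_train = y[train_mask]
        if len(np.unique(y_train)) < 2 or len(np.unique(y[test_mask])) < 1:
            logger.warning("fold %d skipped: single-class training data", k)
            continue
        X_train, X_test = X.loc[train_mask], X.loc[test_mask]
        if selector is not None:
            ranked = rank_features(X_train, y_train, selector)
            if selector == "cfs" or top_fraction is None:
                chosen = ranked.names
            else:
                chosen = select_top_fraction(ranked, X.shape[1], top_fraction)
            report.selected_features.append(chosen)
            X_train, X_test = X_train[chosen], X_test[chosen]
        model = train_classifier(classifier, X_train, y_train, seed=seed)
        probs = model.prob_up(X_test)
        preds = model.predict(X_test)
        y_test = y[test_mask]
        f_tp = int(((preds == POSITIVE_CLASS) & (y_test == POSITIVE_CLASS)).sum())
        f_fp = int(((preds == POSITIVE_CLASS) & (y_test != POSITIVE_CLASS)).sum())
        f_fn = int(((preds != POSITIVE_CLASS) & (y_test == POSITIVE_CLASS)).sum())
        f_tn = int(((preds != POSITIVE_CLASS) & (y_test != POSITIVE_CLASS)).sum())
        tp, fp, fn, tn = tp + f_tp, fp + f_fp, fn + f_fn, tn + f_tn
        report.fold_metrics.append(compute_metrics(f_tp, f_fp, f_fn, f_tn))
        pooled_scores.extend(probs.tolist())
        pooled_labels.extend(y_test.tolist())
    if not report.fold_metrics:
        raise ValueError("no usable folds")
    report.pooled = compute_metrics(tp, fp, fn, tn)
    if len(set(pooled_labels)) == 2:
        report.auc, _ = roc_auc(pooled_scores, pooled_labels)
    return report
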