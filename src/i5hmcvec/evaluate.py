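"""Performance evaluation.

Binary-classification statistics over a confusion tally —

    Sen = TP / (TP + FN)                    (sensitivity / recall)
    Spe = TN / (TN + FP)                    (specificity)
    Acc = (TP + TN) / (TP + TN + FP + FN)   (accuracy)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP))

— plus threshold-free ROC and precision-recall curves (AUROC by the
trapezoid rule, AUPR by step interpolation), the 10x5 repeated stratified
cross-validation protocol, and the length-resolution analysis that probes
how short an input the region-level model still rejects reliably.

When any MCC denominator factor is zero the coefficient is reported as 0
with an explicit flag (a common convention for the undefined case).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .dataset import GenomicInterval, extract_sequence
from .encoder import encode
from .embeddings import MultiKEmbeddings
from .errors import (
    InvalidInputError,
    TooShortError,
    UnencodableSequenceError,
)

__all__ = [
    "ConfusionCounts",
    "MetricsScores",
    "MetricsReport",
    "RocPrResult",
    "confusion",
    "metrics",
    "roc_pr",
    "repeated_cv",
    "resolution_analysis",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ["sen", "spe", "acc", "mcc", "auroc", "aupr"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsScores:
    sen: float
    spe: float
    acc: float
    mcc: float
    mcc_defined: bool = True


def confusion(labels_true: Sequence[int], labels_pred: Sequence[int]) -> ConfusionCounts:
    """Exhaustive TP/TN/FP/FN tally of binary labels."""
    y = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    if y.shape != p.shape or y.ndim != 1:
        raise InvalidInputError("labels must be 1-D and of equal length")
    if y.size == 0:
        raise InvalidInputError("cannot tally an empty label set")
    if not (set(np.unique(y)) | set(np.unique(p))) <= {0, 1}:
        raise InvalidInputError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def metrics(cc: ConfusionCounts) -> MetricsScores:
    """Sen, Spe, Acc and MCC from a confusion tally."""
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / cc.total if cc.total else float("nan")
    den = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    if den == 0:
        mcc, defined = 0.0, False
    else:
        mcc, defined = (tp * tn - fp * fn) / math.sqrt(den), True
    return MetricsScores(sen=sen, spe=spe, acc=acc, mcc=mcc, mcc_defined=defined)


@dataclass
class RocPrResult:
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auroc: float
    aupr: float


def roc_pr(labels_true: Sequence[int], scores: Sequence[float]) -> RocPrResult:
    """ROC and PR curves with their areas.

    Thresholds sweep the unique score values (ties collapse to a single
    threshold).  AUROC integrates the ROC curve by the trapezoid rule;
    AUPR uses the step-interpolated (average-precision) form.
    """
    y = np.asarray(labels_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise InvalidInputError("labels and scores must be 1-D and aligned")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present for ROC/PR")
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    return RocPrResult(
        fpr=fpr,
        tpr=tpr,
        precision=precision,
        recall=recall,
        auroc=float(roc_auc_score(y, s)),
        aupr=float(average_precision_score(y, s)),
    )


@dataclass
class MetricsReport:
    """Per-repeat cross-validation metrics with mean and sd across repeats."""

    per_repeat: pd.DataFrame  # one row per repeat, columns METRIC_NAMES
    mean: dict[str, float]
    sd: dict[str, float]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": METRIC_NAMES,
                "mean": [self.mean[m] for m in METRIC_NAMES],
                "sd": [self.sd[m] for m in METRIC_NAMES],
            }
        )


def repeated_cv(
    features: np.ndarray,
    labels: np.ndarray,
    model_factory: Callable[[int], object],
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Repeated stratified k-fold cross-validation (default 10 x 5-fold).

    Folds are reshuffled per repeat from the seed.  Within a repeat the
    held-out predictions of all folds are pooled and scored once, then
    mean and sd are taken across repeats.  ``model_factory(seed)`` must
    return an unfitted model exposing ``fit``, ``predict`` and
    ``decision_scores``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present")
    if folds > min(np.bincount(y)):
        raise InvalidInputError("folds exceed the size of the smaller class")

    rows = []
    for r in range(repeats):
        rep_seed = (seed + 7919 * r) % 2**31
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        oof_pred = np.empty_like(y)
        oof_score = np.empty(y.size, dtype=float)
        for train_idx, test_idx in skf.split(X, y):
            model = model_factory(rep_seed)
            model.fit(X[train_idx], y[train_idx])
            oof_pred[test_idx] = model.predict(X[test_idx])
            oof_score[test_idx] = model.decision_scores(X[test_idx])
        scores = metrics(confusion(y, oof_pred))
        curve = roc_pr(y, oof_score)
        rows.append(
            {
                "sen": scores.sen,
                "spe": scores.spe,
                "acc": scores.acc,
                "mcc": scores.mcc,
                "auroc": curve.auroc,
                "aupr": curve.aupr,
            }
        )
    per_repeat = pd.DataFrame(rows)
    mean = {m: float(per_repeat[m].mean()) for m in METRIC_NAMES}
    sd = {
        m: float(per_repeat[m].std(ddof=1)) if repeats > 1 else 0.0
        for m in METRIC_NAMES
    }
    return MetricsReport(per_repeat=per_repeat, mean=mean, sd=sd)


def _pool_gaps(
    pool: Sequence[GenomicInterval], exclude: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Subtract excluded regions from pool intervals (per chromosome)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclude:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    gaps: list[GenomicInterval] = []
    for region in pool:
        spans = sorted(
            (max(b.start, region.start), min(b.end, region.end))
            for b in by_chrom.get(region.chrom, [])
            if b.overlaps(region)
        )
        cursor = region.start
        for s, e in spans:
            if s > cursor:
                gaps.append(
                    GenomicInterval(region.chrom, cursor, s, region.strand)
                )
            cursor = max(cursor, e)
        if cursor < region.end:
            gaps.append(
                GenomicInterval(region.chrom, cursor, region.end, region.strand)
            )
    return gaps


def resolution_analysis(
    model,
    genome: Mapping[str, str],
    negative_pool: Sequence[GenomicInterval],
    multik: MultiKEmbeddings,
    length_grid: Sequence[int],
    n_per_length: int = 30,
    exclude: Sequence[GenomicInterval] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Specificity of a trained model on negatives of controlled lengths.

    For every requested length, ``n_per_length`` windows are sampled
    uniformly (with replacement over feasible start positions) from the
    negative pool after subtracting ``exclude`` — pass the benchmark
    negatives and peaks there so the probe regions share no interval with
    the training material.  Spe at a length is the fraction of windows
    the model calls negative.  Infeasible lengths are skipped with a
    warning.  Returns a table with columns ``length``, ``spe``, ``n``.
    """
    rng = np.random.default_rng(seed)
    gaps = _pool_gaps(negative_pool, exclude)
    rows = []
    for length in length_grid:
        feasible = [g for g in gaps if g.length >= length]
        total = sum(g.length - length + 1 for g in feasible)
        if total == 0:
            logger.warning("no pool region can host a %d nt window; skipped", length)
            continue
        preds = []
        for _ in range(n_per_length):
            draw = int(rng.integers(total))
            for g in feasible:
                n_starts = g.length - length + 1
                if draw < n_starts:
                    window = GenomicInterval(
                        g.chrom, g.start + draw, g.start + draw + length, g.strand
                    )
                    break
                draw -= n_starts
            try:
                vec = encode(extract_sequence(genome, window), multik).values
            except (TooShortError, UnencodableSequenceError):
                # a very short window may hold no in-vocabulary k-mer
                continue
            preds.append(int(model.predict(vec[None, :])[0]))
        if not preds:
            logger.warning("no encodable %d nt window was drawn; skipped", length)
            continue
        preds_arr = np.asarray(preds)
        rows.append(
            {
                "length": int(length),
                "spe": float((preds_arr == 0).mean()),
                "n": int(preds_arr.size),
            }
        )
    return pd.DataFrame(rows)
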