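"""Evaluation protocol: stratified 5-fold cross-validation, confusion-count
metrics, ROC/AUC, reader precision, and localization hit scoring.

The cross-validation rotation follows the K1..K5 scheme: each fold in
turn is the test set while the other four train, and the reported result
is the arithmetic mean of the five per-fold evaluations. Folds are
stratified by label (so near-balanced data stays balanced per fold) and
seeded for reproducibility.

Metric definitions from the confusion counts tp/tn/fp/fn:

    ACC = (tp+tn)/total    Pre = tp/(tp+fp)    Recall = tp/(tp+fn)
    Spe = tn/(tn+fp)       F1  = 2*Pre*Recall/(Pre+Recall)

A metric whose denominator is zero is reported as *undefined* (None,
with a flag), never coerced to 0 — that would silently bias fold means.
AUC uses the probability-of-injury score with tie-aware threshold
sweeping (trapezoidal integration), which equals the Mann-Whitney
statistic: the probability that a random injured case outscores a random
healthy one, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import ndimage
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.metrics import roc_curve as _sk_roc_curve

from .weakloc import LocalizationMap
from ._tensor import resize_bilinear_array

__all__ = [
    "FoldSplit",
    "ConfusionCounts",
    "MetricsReport",
    "ROCCurve",
    "CrossValidationResult",
    "make_folds",
    "compute_metrics",
    "roc_auc",
    "precision_from_counts",
    "localization_score",
    "cross_validate",
    "round_half_up",
]


def round_half_up(x: float, places: int = 4) -> float:
    """Decimal half-up rounding used for report display."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """k disjoint folds of case ids covering the dataset."""

    folds: list[list]
    seed: int
    stratified: bool

    @property
    def k(self) -> int:
        return len(self.folds)

    def rotation(self):
        """Yield (fold_index, test_ids, train_ids) per the K1..Kk scheme."""
        for j, test in enumerate(self.folds):
            train = [i for jj, f in enumerate(self.folds) if jj != j for i in f]
            yield j, list(test), train


def make_folds(labels, k: int = 5, seed: int = 0, ids=None,
               stratified: bool = True) -> FoldSplit:
    """Shuffle (seeded), stratify by label, and deal ``k`` folds.

    ``ids`` defaults to positional indices. Fold sizes differ by at most
    one, and per-fold class counts differ from exact proportionality by
    at most one.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} cases, got {n}")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    if len(ids) != n:
        raise ValueError("ids and labels must have equal length")
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [list(ids[test_idx]) for _, test_idx in splitter.split(ids, y)]
    return FoldSplit(folds=folds, seed=seed, stratified=stratified)


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionCounts":
        y = np.asarray(labels).astype(int)
        p = np.asarray(predicted).astype(int)
        if y.shape != p.shape:
            raise ValueError("labels and predictions must align")
        return cls(
            tp=int(((y == 1) & (p == 1)).sum()),
            tn=int(((y == 0) & (p == 0)).sum()),
            fp=int(((y == 0) & (p == 1)).sum()),
            fn=int(((y == 1) & (p == 0)).sum()),
        )


@dataclass
class MetricsReport:
    """The six Table-style scores; undefined entries are None + flagged."""

    acc: float | None = None
    pre: float | None = None
    recall: float | None = None
    spe: float | None = None
    f1: float | None = None
    auc: float | None = None
    flags: list[str] = dc_field(default_factory=list)

    def rounded(self, places: int = 4) -> dict:
        return {
            name: (None if v is None else round_half_up(v, places))
            for name, v in self.as_dict().items()
        }

    def as_dict(self) -> dict:
        return {"acc": self.acc, "pre": self.pre, "recall": self.recall,
                "spe": self.spe, "f1": self.f1, "auc": self.auc}


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, specificity and F1 from counts."""
    if c.total <= 0:
        raise ValueError("metric computation needs at least one case")
    rep = MetricsReport()
    rep.acc = (c.tp + c.tn) / c.total
    if c.tp + c.fp > 0:
        rep.pre = c.tp / (c.tp + c.fp)
    else:
        rep.flags.append("precision undefined (tp+fp=0)")
    if c.tp + c.fn > 0:
        rep.recall = c.tp / (c.tp + c.fn)
    else:
        rep.flags.append("recall undefined (tp+fn=0)")
    if c.tn + c.fp > 0:
        rep.spe = c.tn / (c.tn + c.fp)
    else:
        rep.flags.append("specificity undefined (tn+fp=0)")
    if rep.pre is not None and rep.recall is not None and rep.pre + rep.recall > 0:
        rep.f1 = 2 * rep.pre * rep.recall / (rep.pre + rep.recall)
    else:
        rep.flags.append("f1 undefined")
    return rep


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(labels, scores) -> ROCCurve:
    """Threshold-sweep ROC curve with trapezoidal AUC.

    Ties receive half credit (the trapezoid over a tied block), so the
    area equals the Mann-Whitney probability that a random positive
    outscores a random negative.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    present = set(np.unique(y))
    for cls in (0, 1):
        if cls not in present:
            raise ValueError(f"ROC requires both classes; class {cls} is missing")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def precision_from_counts(correct: int, total: int) -> float:
    """Reader-study precision as a percentage: 100 * correct / total."""
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not 0 <= correct <= total:
        raise ValueError(f"need 0 <= correct <= total, got {correct}/{total}")
    return 100.0 * correct / total


# ---------------------------------------------------------------------------
# localization scoring
# ---------------------------------------------------------------------------

def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def localization_score(loc, mask: np.ndarray, dilation_radius: int = 9) -> bool:
    """Hit test: does the map peak fall inside the dilated lesion mask?

    The map is resized to the mask resolution; its argmax (first raster
    index on ties) must lie within the mask dilated by a disk of the
    given pixel radius.
    """
    values = loc.values if isinstance(loc, LocalizationMap) else np.asarray(loc)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("localization_score requires a nonempty lesion mask")
    if values.shape != mask.shape:
        values = resize_bilinear_array(values, mask.shape)
    peak = np.unravel_index(int(values.argmax()), values.shape)
    dilated = ndimage.binary_dilation(mask, structure=_disk(dilation_radius))
    return bool(dilated[peak])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    per_fold: list[MetricsReport]
    mean: MetricsReport
    counts: list[ConfusionCounts]
    folds: FoldSplit

    def as_table(self) -> list[dict]:
        rows = [dict(fold=j, **rep.rounded()) for j, rep in enumerate(self.per_fold)]
        rows.append(dict(fold="mean", **self.mean.rounded()))
        return rows


def _mean_metrics(reports: list[MetricsReport]) -> MetricsReport:
    mean = MetricsReport()
    for name in ("acc", "pre", "recall", "spe", "f1", "auc"):
        vals = [getattr(r, name) for r in reports]
        defined = [v for v in vals if v is not None]
        if defined:
            setattr(mean, name, float(np.mean(defined)))
        if len(defined) < len(vals):
            mean.flags.append(f"{name} undefined in {len(vals) - len(defined)} fold(s)")
    return mean


def cross_validate(cases, config, k: int = 5, seed: int = 0,
                   train_fn=None, predict_fn=None) -> CrossValidationResult:
    """K-fold rotation: train on k-1 folds, test on the held-out one.

    ``train_fn(cases, config)`` and ``predict_fn(model, cases)`` default
    to the cascade's training/prediction and exist for evaluating other
    classifiers under the identical protocol.
    """
    if train_fn is None or predict_fn is None:
        from . import cascade as _cascade

        train_fn = train_fn or _cascade.train
        predict_fn = predict_fn or _cascade.predict
    cases = list(cases)
    labels = [c.label for c in cases]
    split = make_folds(labels, k=k, seed=seed)
    per_fold, counts = [], []
    for j, test_ids, train_ids in split.rotation():
        model = train_fn([cases[i] for i in train_ids], config)
        preds = predict_fn(model, [cases[i] for i in test_ids])
        y = np.array([cases[i].label for i in test_ids])
        yhat = np.array([p.label for p in preds])
        scores = np.array([p.probability for p in preds])
        c = ConfusionCounts.from_predictions(y, yhat)
        rep = compute_metrics(c)
        if len(set(y)) == 2:
            rep.auc = roc_auc(y, scores).auc
        else:
            rep.flags.append(f"auc undefined for fold {j} (single-class test set)")
        per_fold.append(rep)
        counts.append(c)
    return CrossValidationResult(per_fold=per_fold, mean=_mean_metrics(per_fold),
                                 counts=counts, folds=split)
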