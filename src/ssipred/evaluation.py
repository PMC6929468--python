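"""Confusion counting, the six classification metrics, stratified CV with
labeled/unlabeled masking, and fold-stability summaries.

Metrics: accuracy, sensitivity (recall on interface residues), precision,
specificity, F-measure (harmonic mean of precision and sensitivity) and
Matthews correlation coefficient.  Positives are interface residues (+1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "specificity", "f_measure", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f_measure: float
    mcc: float
    #: metrics whose denominator was zero (value reported as 0)
    undefined: tuple = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion(pred, truth) -> ConfusionCounts:
    """Count TP/TN/FP/FN between +-1 prediction and truth vectors."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    return ConfusionCounts(
        TP=int(np.sum((pred > 0) & (truth > 0))),
        TN=int(np.sum((pred < 0) & (truth < 0))),
        FP=int(np.sum((pred > 0) & (truth < 0))),
        FN=int(np.sum((pred < 0) & (truth > 0))),
    )


def _ratio(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """The six metrics from the confusion counts.

    A metric whose denominator is zero is reported as 0 and flagged in
    ``undefined`` so fold aggregation stays total.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    undef: list = []
    acc = (c.TP + c.TN) / c.total
    sens = _ratio(c.TP, c.TP + c.FN, "sensitivity", undef)
    prec = _ratio(c.TP, c.TP + c.FP, "precision", undef)
    spec = _ratio(c.TN, c.FP + c.TN, "specificity", undef)
    f = _ratio(2 * prec * sens, prec + sens, "f_measure", undef)
    mcc_den = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "mcc", undef)
    return MetricReport(acc, sens, prec, spec, f, mcc, tuple(undef))


def mask_unlabeled(y_train: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Boolean mask of training samples whose labels are hidden.

    One sample per class is always kept labeled so every learner stays
    well-posed.
    """
    n = len(y_train)
    mask = np.zeros(n, dtype=bool)
    if fraction <= 0 or n == 0:
        return mask
    keep = set()
    for cls in (1, -1):
        idx = np.nonzero(y_train == cls)[0]
        if len(idx):
            keep.add(int(rng.choice(idx)))
    eligible = np.array([i for i in range(n) if i not in keep])
    n_mask = min(int(round(fraction * n)), len(eligible))
    if n_mask > 0:
        chosen = rng.choice(eligible, size=n_mask, replace=False)
        mask[chosen] = True
    return mask


def cross_validate(X, y, learner, folds: int = 5, unlabeled_fraction: float = 0.7,
                   seed: int = 0) -> list[MetricReport]:
    """Stratified k-fold CV with semi-supervised masking of the training split.

    ``learner`` is a callable (X_l, y_l, X_u, X_test) -> +-1 predictions on
    X_test.  Within each training split a seeded ``unlabeled_fraction`` of
    samples enters the unlabeled pool; the test fold is never used to train.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    reports = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {k}: a class is absent after stratification")
        mask = mask_unlabeled(y_tr, unlabeled_fraction, rng)
        X_l, y_l = X[tr][~mask], y_tr[~mask]
        X_u = X[tr][mask]
        pred = learner(X_l, y_l, X_u, X[te])
        reports.append(metrics(confusion(pred, y[te])))
    return reports


def stability(per_fold: list[MetricReport]) -> dict:
    """Per-metric absolute deviations from the cross-fold mean.

    Returns {metric: {"values", "mean", "deviations", "max_dev", "mean_dev"}} —
    the fluctuation summary used to judge fold-to-fold robustness.
    """
    if len(per_fold) < 2:
        raise ValueError("need at least 2 folds")
    out = {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in per_fold])
        mean = vals.mean()
        dev = np.abs(vals - mean)
        out[m] = {
            "values": vals,
            "mean": float(mean),
            "deviations": dev,
            "max_dev": float(dev.max()),
            "mean_dev": float(dev.mean()),
        }
    return out
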