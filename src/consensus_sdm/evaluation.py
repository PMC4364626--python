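"""Presence-absence model evaluation: AUC, Cohen's kappa, TSS, and the
model-retention filter.

AUC is threshold-independent (the probability that a random presence
outranks a random absence); kappa and TSS are computed from the confusion
table at the fixed 0.5 presence threshold used throughout the pipeline.
Models are retained only if AUC >= 0.70 and kappa >= 0.4 and TSS >= 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

AUC_THRESHOLD = 0.70
KAPPA_THRESHOLD = 0.4
TSS_THRESHOLD = 0.4
PRESENCE_THRESHOLD = 0.5


@dataclass
class ConfusionCounts:
    """2x2 confusion table: a=TP, b=FP, c=FN, d=TN, at a stated threshold."""

    a: int
    b: int
    c: int
    d: int
    threshold: float = PRESENCE_THRESHOLD

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EvaluationScores:
    auc: float
    kappa: float
    tss: float

    @property
    def passed(self) -> bool:
        return (
            self.auc >= AUC_THRESHOLD
            and self.kappa >= KAPPA_THRESHOLD
            and self.tss >= TSS_THRESHOLD
        )


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if labels.all() or not labels.any():
        raise ValueError("labels contain a single class; metric undefined")
    return labels


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score+ > score-) + 0.5 P(tie), via midranks.

    Equivalent to the normalized Mann-Whitney U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    ranks = rankdata(scores)  # midranks
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion(scores, labels, threshold: float = PRESENCE_THRESHOLD) -> ConfusionCounts:
    """Tally the 2x2 table; presence is predicted iff score > threshold
    (strictly — a score exactly at the threshold predicts absence)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size == 0:
        raise ValueError("empty input")
    pred = scores > threshold
    return ConfusionCounts(
        a=int((pred & labels).sum()),
        b=int((pred & ~labels).sum()),
        c=int((~pred & labels).sum()),
        d=int((~pred & ~labels).sum()),
        threshold=threshold,
    )


def kappa(cm: ConfusionCounts) -> float:
    """Cohen's kappa: chance-corrected agreement of the 2x2 table."""
    n = cm.n
    po = (cm.a + cm.d) / n
    pe = ((cm.a + cm.b) * (cm.a + cm.c) + (cm.c + cm.d) * (cm.b + cm.d)) / n**2
    if pe == 1.0:
        raise ValueError("degenerate margins: expected agreement is 1, kappa undefined")
    return float((po - pe) / (1.0 - pe))


def tss(cm: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if cm.a + cm.c == 0 or cm.b + cm.d == 0:
        raise ValueError("empty margin: observed class missing, TSS undefined")
    return float(cm.a / (cm.a + cm.c) + cm.d / (cm.b + cm.d) - 1.0)


def evaluate(scores, labels, threshold: float = PRESENCE_THRESHOLD) -> EvaluationScores:
    """All three accuracy measures on one testing set."""
    cm = confusion(scores, labels, threshold)
    return EvaluationScores(auc=auc(scores, labels), kappa=kappa(cm), tss=tss(cm))


def filter_models(scores_by_key: dict, *,
                  auc_min: float = AUC_THRESHOLD,
                  kappa_min: float = KAPPA_THRESHOLD,
                  tss_min: float = TSS_THRESHOLD,
                  ) -> tuple[list, list]:
    """Partition model keys into (retained, removed) by the conjunction
    AUC >= auc_min and kappa >= kappa_min and TSS >= tss_min.

    ``scores_by_key`` maps any hashable model key to EvaluationScores (or
    None for a failed fit, which is always removed). Fails explicitly if no
    model survives.
    """
    retained, removed = [], []
    for key, sc in scores_by_key.items():
        ok = (
            sc is not None
            and sc.auc >= auc_min
            and sc.kappa >= kappa_min
            and sc.tss >= tss_min
        )
        (retained if ok else removed).append(key)
    if not retained:
        raise RuntimeError("no model passed evaluation filter")
    return retained, removed
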