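"""Confusion matrices, the screening metric suite and ROC/AUC.

The metric set summarises a binary screen on an imbalanced cohort::

    AC   = (TP + TN) / (TP + FP + TN + FN)
    SENS = TP / (TP + FN)
    SPEC = TN / (TN + FP)
    F    = 2 * SENS * SPEC / (SENS + SPEC)   (harmonic mean)
    G    = sqrt(SENS * SPEC)                 (geometric mean)

F and G deliberately ignore the class sizes, so a model that sacrifices the
tiny positive class for bulk accuracy scores poorly.  Exact values are kept
internally; :meth:`MetricsReport.as_printed` reproduces the publication
table convention, where F and G are computed from the already-rounded
SENS/SPEC (the only reading consistent with every printed table cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for a binary screen; positive class = cancer."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The matrix with the positive-class designation exchanged."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def confusion(
    true_labels, predicted_labels, pos_label="positive", neg_label="control"
) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors differ in length")
    allowed = {pos_label, neg_label}
    bad = (set(true_labels) | set(predicted_labels)) - allowed
    if bad:
        raise ValueError(f"unknown labels {sorted(map(str, bad))}; expected {sorted(map(str, allowed))}")
    t_pos = true_labels == pos_label
    p_pos = predicted_labels == pos_label
    return ConfusionMatrix(
        tp=int(np.sum(t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Exact metric values; ``None`` marks an undefined (0/0) metric."""

    ac: float | None
    sens: float | None
    spec: float | None
    f: float | None
    g: float | None
    auc: float | None = None

    def as_printed(self, ndigits: int = 2) -> dict:
        """Round for display the way the result tables are printed.

        SENS and SPEC are rounded (half-up) first; F and G are then the
        harmonic/geometric mean of the *rounded* values, rounded again.
        """
        sens = _round_half_up(self.sens, ndigits)
        spec = _round_half_up(self.spec, ndigits)
        f = g = None
        if sens is not None and spec is not None:
            f = _round_half_up(
                2 * sens * spec / (sens + spec) if sens + spec > 0 else 0.0, ndigits
            )
            g = _round_half_up(math.sqrt(sens * spec), ndigits)
        return {
            "AC": _round_half_up(self.ac, ndigits),
            "SENS": sens,
            "SPEC": spec,
            "F": f,
            "G": g,
        }


def _round_half_up(x: float | None, ndigits: int) -> float | None:
    if x is None:
        return None
    shift = 10.0**ndigits
    return math.floor(x * shift + 0.5) / shift


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """Exact AC/SENS/SPEC/F/G from counts; zero denominators yield ``None``."""
    ac = (cm.tp + cm.tn) / cm.total if cm.total > 0 else None
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    f = g = None
    if sens is not None and spec is not None:
        f = 2 * sens * spec / (sens + spec) if (sens + spec) > 0 else 0.0
        g = math.sqrt(sens * spec)
    return MetricsReport(ac=ac, sens=sens, spec=spec, f=f, g=g, auc=auc)


def roc_auc(decision_scores, true_labels, pos_label="positive") -> float:
    """Area under the ROC curve of the decision scores.

    Equals the Mann-Whitney U statistic normalised by ``n_pos * n_neg``,
    with tied scores credited one half.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    y = (true_labels == pos_label).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(decision_scores, dtype=float)))
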