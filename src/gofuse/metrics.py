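"""Protein-centric CAFA-style evaluation: F-max, AUPR and ROC AUC.

F-max scans a threshold grid t in [0, 1]. At each t a protein's predicted
term set is {terms with score >= t}; per-protein precision is averaged over
the m(t) proteins with a non-empty prediction set, per-protein recall over the
annotated proteins, and F-max is the best harmonic mean across the grid.
AUPR and AUC are computed over the pooled protein x term score/label pairs
(micro) by default, with a per-term macro mode.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_area
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .errors import EvaluationError

#: CAFA-style threshold grid: 0.00, 0.01, ..., 1.00.
DEFAULT_THRESHOLDS = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Precision/recall at one threshold, with the protein counts behind them."""

    t: float
    precision: float
    recall: float
    m_t: int  # proteins with >= 1 predicted term at t
    n: int    # proteins entering the recall average


@dataclass(frozen=True)
class EvalReport:
    """F-max with its argmax threshold, AUPR, AUC, and the full P-R curve."""

    fmax: float
    fmax_threshold: float
    aupr: float
    auc: float
    curve: List[ThresholdMetrics]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curve"] = [asdict(c) for c in self.curve]
        return d


def _check_pair(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 2:
        raise EvaluationError(
            f"scores {scores.shape} and labels {labels.shape} must be equal 2-D shapes"
        )
    return scores, labels.astype(bool)


def protein_precision_recall(
    pred_row: np.ndarray, true_row: np.ndarray, t: float
) -> tuple[float | None, float | None]:
    """Per-protein precision and recall at threshold ``t``.

    Precision is undefined (None) when the protein predicts no term at ``t``;
    recall is undefined when the protein has no true label.
    """
    pred = np.asarray(pred_row, dtype=float) >= t
    true = np.asarray(true_row).astype(bool)
    overlap = int((pred & true).sum())
    pr = overlap / int(pred.sum()) if pred.any() else None
    rc = overlap / int(true.sum()) if true.any() else None
    return pr, rc


def fmax(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: Sequence[float] | None = None,
    recall_over_all_proteins: bool = False,
) -> tuple[float, float, List[ThresholdMetrics]]:
    """Protein-centric F-max over a threshold grid.

    Returns ``(fmax, best_threshold, curve)``. By default the recall average
    runs over proteins with at least one true label (the CAFA benchmark
    reading); ``recall_over_all_proteins`` switches the denominator to every
    protein in the set.
    """
    scores, labels = _check_pair(scores, labels)
    if not labels.any():
        raise EvaluationError("F-max needs at least one protein with a true label")
    grid = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, dtype=float)

    n_true = labels.sum(axis=1)
    annotated = n_true > 0
    n_recall = int(scores.shape[0] if recall_over_all_proteins else annotated.sum())

    curve: List[ThresholdMetrics] = []
    best, best_t = 0.0, float(grid[0])
    for t in grid:
        pred = scores >= t
        overlap = (pred & labels).sum(axis=1)
        n_pred = pred.sum(axis=1)
        has_pred = n_pred > 0
        m_t = int(has_pred.sum())
        pr_t = float((overlap[has_pred] / n_pred[has_pred]).mean()) if m_t else 0.0
        rc_t = float((overlap[annotated] / n_true[annotated]).sum() / n_recall)
        f_t = (
            2.0 * pr_t * rc_t / (pr_t + rc_t)
            if m_t and (pr_t + rc_t) > 0
            else 0.0
        )
        curve.append(ThresholdMetrics(float(t), pr_t, rc_t, m_t, n_recall))
        if f_t > best:
            best, best_t = f_t, float(t)
    return best, best_t, curve


def aupr(scores: np.ndarray, labels: np.ndarray, average: str = "micro") -> float:
    """Area under the precision-recall curve by the trapezoid rule.

    ``micro`` pools all protein x term pairs; ``macro`` averages per-term
    areas over terms that have at least one positive.
    """
    scores, labels = _check_pair(scores, labels)
    if not labels.any():
        raise EvaluationError("AUPR needs at least one positive pair")
    if average == "micro":
        return _aupr_pairs(scores.ravel(), labels.ravel())
    if average == "macro":
        areas = [
            _aupr_pairs(scores[:, j], labels[:, j])
            for j in range(labels.shape[1])
            if labels[:, j].any()
        ]
        return float(np.mean(areas))
    raise EvaluationError(f"unknown averaging mode {average!r}")


def _aupr_pairs(s: np.ndarray, y: np.ndarray) -> float:
    precision, recall, _ = precision_recall_curve(y.astype(int), s)
    # precision_recall_curve returns the curve in decreasing-recall order
    return float(_trapezoid_area(recall[::-1], precision[::-1]))


def auc(scores: np.ndarray, labels: np.ndarray, average: str = "micro") -> float:
    """Area under the ROC curve; ties follow the rank (Mann-Whitney) convention."""
    scores, labels = _check_pair(scores, labels)
    flat = labels.ravel()
    if average == "micro":
        if flat.all() or not flat.any():
            raise EvaluationError("AUC needs both a positive and a negative pair")
        return float(roc_auc_score(flat.astype(int), scores.ravel()))
    if average == "macro":
        vals = [
            float(roc_auc_score(labels[:, j].astype(int), scores[:, j]))
            for j in range(labels.shape[1])
            if labels[:, j].any() and not labels[:, j].all()
        ]
        if not vals:
            raise EvaluationError("AUC needs both classes in at least one term")
        return float(np.mean(vals))
    raise EvaluationError(f"unknown averaging mode {average!r}")


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: Sequence[float] | None = None,
    average: str = "micro",
) -> EvalReport:
    """Full report: F-max (+argmax threshold and curve), AUPR and AUC."""
    f, t_star, curve = fmax(scores, labels, thresholds)
    return EvalReport(
        fmax=f,
        fmax_threshold=t_star,
        aupr=aupr(scores, labels, average),
        auc=auc(scores, labels, average),
        curve=curve,
    )


def export_pr_curve(curve: Sequence[ThresholdMetrics], path: str | Path) -> None:
    """TSV of (threshold, precision, recall) rows in ascending threshold order."""
    if not curve:
        raise EvaluationError("cannot export an empty P-R curve")
    with open(path, "w") as fh:
        fh.write("threshold\tprecision\trecall\n")
        for pt in sorted(curve, key=lambda c: c.t):
            fh.write(f"{pt.t:.6g}\t{pt.precision:.17g}\t{pt.recall:.17g}\n")


def read_pr_curve(path: str | Path) -> List[tuple[float, float, float]]:
    rows: List[tuple[float, float, float]] = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            t, p, r = line.split("\t")
            rows.append((float(t), float(p), float(r)))
    return rows
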