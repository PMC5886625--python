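"""Performance measures for estimated networks against a known ground truth.

All measures operate on the off-diagonal entries only, since the diagonal
of a coupling estimate is undefined under the model.  Edge detection is
scored with the area under the ROC curve (AUC) and the average-precision
score (PRS, the area under the precision-recall curve), both computed from
the magnitudes |G_est| as continuous scores against binary edge existence.
Strengths and signs are scored with the Pearson correlation coefficient
(PCC) between the signed estimated and true weights.  A thresholded
confusion report supplements these with miss rate FN/(TP+FN), false-alarm
rate FP/(FP+TN), and the sign accuracy among detected edges.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "PerformanceReport",
    "roc_auc",
    "precision_recall_score",
    "pearson",
    "confusion_at_threshold",
    "evaluate",
]


@dataclass
class PerformanceReport:
    """Detection and strength-recovery quality of one estimate."""

    auc: float
    prs: float
    pcc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    fn_rate: float
    fp_rate: float
    fn_fraction: float
    fp_fraction: float
    sign_accuracy: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _offdiag(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G)
    n = G.shape[0]
    if G.shape != (n, n):
        raise ValueError(f"expected a square matrix, got shape {G.shape}")
    return G[~np.eye(n, dtype=bool)]


def _detection_vectors(G_est: np.ndarray, G_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    est, true = np.asarray(G_est), np.asarray(G_true)
    if est.shape != true.shape:
        raise ValueError(f"shape mismatch: estimate {est.shape} vs truth {true.shape}")
    scores = np.abs(_offdiag(est))
    labels = _offdiag(true) != 0
    if labels.all() or not labels.any():
        raise ValueError(
            "ground truth has no edges or only edges: detection metrics are undefined"
        )
    return scores, labels


def roc_auc(G_est: np.ndarray, G_true: np.ndarray) -> float:
    """Area under the ROC curve of |G_est| as edge-detection scores."""
    scores, labels = _detection_vectors(G_est, G_true)
    return float(roc_auc_score(labels, scores))


def precision_recall_score(G_est: np.ndarray, G_true: np.ndarray) -> float:
    """Average precision (area under the precision-recall curve)."""
    scores, labels = _detection_vectors(G_est, G_true)
    return float(average_precision_score(labels, scores))


def pearson(G_est: np.ndarray, G_true: np.ndarray) -> float:
    """Pearson correlation of signed off-diagonal weights.

    Sensitive to strength and sign, unlike the rank-based detection scores.
    """
    est, true = np.asarray(G_est), np.asarray(G_true)
    if est.shape != true.shape:
        raise ValueError(f"shape mismatch: estimate {est.shape} vs truth {true.shape}")
    x, y = _offdiag(est), _offdiag(true)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("a constant weight vector has no defined correlation")
    return float(np.corrcoef(x, y)[0, 1])


def default_threshold(G_true: np.ndarray) -> float:
    """Half the smallest nonzero ground-truth magnitude.

    Networks with equal-magnitude edges make any threshold in (0, |J|)
    equivalent for a perfect estimate; half the edge strength is the
    midpoint of that band.
    """
    mags = np.abs(_offdiag(G_true))
    mags = mags[mags > 0]
    if mags.size == 0:
        raise ValueError("ground truth has no edges")
    return 0.5 * float(mags.min())


def confusion_at_threshold(
    G_est: np.ndarray, G_true: np.ndarray, threshold: float | None = None
) -> PerformanceReport:
    """Full performance report with edges called at |G_est| > threshold.

    Rates follow the ROC conventions: ``fn_rate = FN/(TP+FN)`` (miss rate,
    the complement of recall) and ``fp_rate = FP/(FP+TN)``.
    ``fn_fraction`` and ``fp_fraction`` are the shares of all off-diagonal
    entries of the estimated connection matrix that are false negatives and
    false positives (FN/N_offdiag, FP/N_offdiag) — the natural summary when
    misclassifications are counted against the whole matrix rather than
    against one class.  ``sign_accuracy`` is the fraction of true positives
    whose estimated sign matches the ground truth (NaN when nothing is
    detected).
    """
    if threshold is None:
        threshold = default_threshold(G_true)
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    est, true = np.asarray(G_est, dtype=float), np.asarray(G_true, dtype=float)
    e, t = _offdiag(est), _offdiag(true)
    called = np.abs(e) > threshold
    actual = t != 0
    tp = int(np.sum(called & actual))
    fp = int(np.sum(called & ~actual))
    tn = int(np.sum(~called & ~actual))
    fn = int(np.sum(~called & actual))
    fn_rate = fn / (tp + fn) if (tp + fn) else float("nan")
    fp_rate = fp / (fp + tn) if (fp + tn) else float("nan")
    n_pairs = tp + fp + tn + fn
    tp_mask = called & actual
    sign_accuracy = (
        float(np.mean(np.sign(e[tp_mask]) == np.sign(t[tp_mask]))) if tp else float("nan")
    )
    return PerformanceReport(
        auc=roc_auc(est, true),
        prs=precision_recall_score(est, true),
        pcc=pearson(est, true),
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        fn_rate=fn_rate,
        fp_rate=fp_rate,
        fn_fraction=fn / n_pairs,
        fp_fraction=fp / n_pairs,
        sign_accuracy=sign_accuracy,
    )


# the thresholded report carries every measure; expose it under a generic name
evaluate = confusion_at_threshold
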