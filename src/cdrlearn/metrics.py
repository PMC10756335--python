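"""Ranking metrics for the binary sensitive/resistant task."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import ValidationError


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, AUPR) of scores against binary labels.

    AUC is the tie-corrected Mann-Whitney statistic (ties between a positive
    and a negative score count 1/2); AUPR is the step-integrated area under
    the precision-recall curve.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError(f"scores/labels length mismatch: {scores.shape} vs {labels.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValidationError(
            "AUC/AUPR undefined with a single class; use stratified folds or another seed"
        )
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))
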