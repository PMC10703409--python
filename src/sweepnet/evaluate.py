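"""Evaluation metrics and cross-method comparison matrices.

Accuracy intervals use the normal-approximation binomial CI
``p +/- 1.96 * sqrt(p (1 - p) / N)``; ranking quality uses the ROC AUC
(rank / Mann-Whitney statistic with tie correction); methods are compared
by Spearman rank correlation of their continuous scores and by binary
agreement (the fraction of samples on which two classifiers make the same
call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvalReport",
    "MetricError",
    "accuracy_ci",
    "roc_auc",
    "spearman_matrix",
    "agreement_matrix",
    "evaluate_scores",
]


class MetricError(ValueError):
    pass


@dataclass
class EvalReport:
    method: str
    accuracy: float
    ci_low: float
    ci_high: float
    n_test: int
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    calls: np.ndarray = field(repr=False, default=None)

    @property
    def ci_half_width(self) -> float:
        return (self.ci_high - self.ci_low) / 2


def accuracy_ci(n_correct: int, n_total: int, z: float = 1.96) -> tuple[float, float, float]:
    """(p_hat, lower, upper) normal-approximation binomial interval."""
    if n_total <= 0:
        raise MetricError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise MetricError("n_correct out of range")
    p = n_correct / n_total
    half = z * np.sqrt(p * (1 - p) / n_total)
    return p, p - half, p + half


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (tie-corrected rank statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("both classes required for AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _check_named_lists(named: dict[str, np.ndarray], min_len: int = 1) -> dict[str, np.ndarray]:
    arrays = {k: np.asarray(v, dtype=float) for k, v in named.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1:
        raise MetricError("score lists must share one length")
    if lengths.pop() < min_len:
        raise MetricError(f"need at least {min_len} samples")
    return arrays


def spearman_matrix(score_sets: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Symmetric matrix of Spearman rank correlations with unit diagonal."""
    arrays = _check_named_lists(score_sets, min_len=3)
    names = list(arrays)
    k = len(names)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho = sps.spearmanr(arrays[names[i]], arrays[names[j]]).statistic
            mat[i, j] = mat[j, i] = rho
    return mat, names


def agreement_matrix(binary_calls: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Entry (i, j): fraction of samples on which methods i and j agree."""
    arrays = _check_named_lists(binary_calls, min_len=1)
    names = list(arrays)
    k = len(names)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            frac = float(np.mean(arrays[names[i]] == arrays[names[j]]))
            mat[i, j] = mat[j, i] = frac
    return mat, names


def evaluate_scores(
    method: str,
    scores: np.ndarray,
    labels: np.ndarray,
    calls: np.ndarray | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Accuracy (with CI) and AUC of continuous scores against labels.

    When ``calls`` is omitted, scores above ``threshold`` are called sweep.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if calls is None:
        calls = (scores > threshold).astype(int)
    n_correct = int(np.count_nonzero(calls == labels))
    p, lo, hi = accuracy_ci(n_correct, len(labels))
    return EvalReport(
        method=method,
        accuracy=p,
        ci_low=lo,
        ci_high=hi,
        n_test=len(labels),
        auc=roc_auc(scores, labels),
        scores=scores,
        calls=np.asarray(calls, dtype=int),
    )
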