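"""Evaluation metrics implemented directly from their defining formulas.

R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
MSE = (1/n) sum (y_i - yhat_i)^2
ACC = correct predictions / total predictions
ROC-AUC via the rank (Mann-Whitney) formulation, ties counting 1/2.

These are deliberately written out rather than delegated, and are
cross-checked against scikit-learn/scipy in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (zero variance, single class)."""


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("R^2 undefined: target has zero variance")
    sse = float(np.sum((y - y_hat) ** 2))
    return 1.0 - sse / sst


def mean_squared_error(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.mean((y - y_hat) ** 2))


def accuracy(y: np.ndarray, y_pred: np.ndarray) -> float:
    y = np.asarray(y)
    y_pred = np.asarray(y_pred)
    return float(np.mean(y == y_pred))


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC undefined: only one class present")
    ranks = rankdata(scores)          # midranks handle ties
    rank_sum_pos = float(ranks[y == 1].sum())
    u_pos = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u_pos / (n_pos * n_neg)
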