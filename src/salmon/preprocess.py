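"""Two-step expression filtering applied before co-expression analysis.

Both filters interpret "lowest X%" as a count: exactly ``floor(fraction * n)``
features are removed, with ties at the boundary broken by (statistic, original
row index) under a stable sort.  Surviving values are never altered.
"""

from __future__ import annotations

import numpy as np

from .data_model import ExpressionMatrix

__all__ = ["filter_by_mean", "filter_by_variance"]


def _filter_by_stat(expr: ExpressionMatrix, stat: np.ndarray, fraction: float) -> ExpressionMatrix:
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if expr.n_features == 0:
        raise ValueError("expression matrix has no features")
    n_remove = int(np.floor(fraction * expr.n_features))
    if n_remove == 0:
        return expr
    # stable sort => ties broken by original row index
    order = np.argsort(stat, kind="stable")
    drop = set(order[:n_remove].tolist())
    keep = [i for i in range(expr.n_features) if i not in drop]
    return expr.subset_features(keep)


def filter_by_mean(expr: ExpressionMatrix, fraction: float = 0.2) -> ExpressionMatrix:
    """Remove the ``floor(fraction * n)`` features with the smallest row means."""
    return _filter_by_stat(expr, expr.values.mean(axis=1), fraction)


def filter_by_variance(expr: ExpressionMatrix, fraction: float = 0.2) -> ExpressionMatrix:
    """Remove the ``floor(fraction * n)`` features with the smallest row
    variances (unbiased, divisor n-1)."""
    if expr.n_samples < 2:
        raise ValueError("variance filter needs at least 2 samples")
    return _filter_by_stat(expr, expr.values.var(axis=1, ddof=1), fraction)
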