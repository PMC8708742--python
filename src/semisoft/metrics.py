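"""Prediction-quality metrics: RMSE and the coefficient of determination.

R² uses the standard denominator Σ(y_n − ȳ)² with ȳ the mean of the
observed output.  For a constant truth vector the denominator vanishes and
R² is undefined; ``nan`` is returned with a warning rather than raising.
"""

from __future__ import annotations

import warnings

import numpy as np


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    if y_true.size == 0:
        raise ValueError("empty vectors")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error sqrt(mean((y - yhat)^2))."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r2(y_true, y_pred) -> float:
    """Coefficient of determination 1 − SS_res / SS_tot."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined for constant truth; returning nan")
        return float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot
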