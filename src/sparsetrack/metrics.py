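"""Evaluation functionals for estimated versus true mixing proportions.

Three quantities summarize a fit against ground truth:

* ``mse`` — sum over the M known sources of squared proportion deviations
  (a sum, not a mean, matching the benchmark convention; pass
  ``mean=True`` for the conventional definition).
* ``abs_error_unknown`` — absolute error on the unknown proportion.
* ``false_positive_rate`` — total estimated mass on sources whose true
  contribution is exactly zero; together with the mass on true sources and
  the estimated unknown this partitions the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationReport",
    "mse",
    "abs_error_unknown",
    "false_positive_rate",
    "evaluate",
]


@dataclass
class EvaluationReport:
    mse: float
    ae_unknown: float
    fpr: float
    per_source_residuals: np.ndarray


def _check_pair(alpha_true: np.ndarray, alpha_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(alpha_true, dtype=float)
    h = np.asarray(alpha_hat, dtype=float)
    if t.shape != h.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {h.shape}")
    return t, h


def mse(alpha_true: np.ndarray, alpha_hat: np.ndarray, mean: bool = False) -> float:
    """Sum of squared deviations over the M known sources (mean if asked)."""
    t, h = _check_pair(alpha_true, alpha_hat)
    sq = (t - h) ** 2
    return float(sq.mean() if mean else sq.sum())


def abs_error_unknown(true_unknown: float, est_unknown: float) -> float:
    """Absolute error of the estimated unknown proportion."""
    return float(abs(true_unknown - est_unknown))


def false_positive_rate(alpha_true: np.ndarray, alpha_hat: np.ndarray) -> float:
    """Estimated mass misattributed to truly non-contributing sources.

    Truth zeros are exact (simulated ground truth is constructed, not
    estimated), so no tolerance is applied.
    """
    t, h = _check_pair(alpha_true, alpha_hat)
    return float(h[t == 0].sum())


def evaluate(
    alpha_true_full: np.ndarray, alpha_hat_full: np.ndarray
) -> EvaluationReport:
    """All three metrics from full (M+1)-vectors, unknown entry last."""
    t, h = _check_pair(alpha_true_full, alpha_hat_full)
    return EvaluationReport(
        mse=mse(t[:-1], h[:-1]),
        ae_unknown=abs_error_unknown(t[-1], h[-1]),
        fpr=false_positive_rate(t[:-1], h[:-1]),
        per_source_residuals=np.abs(t[:-1] - h[:-1]),
    )
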