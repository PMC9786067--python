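"""Leverage-based applicability domain (Williams plot data).

A regression QSAR model is only trusted inside the region of descriptor
space it was trained on.  The leverage approach characterises that region
through the hat matrix of the training design: compound i's leverage h_i
measures its distance from the descriptor centroid, and the warning
leverage

    h* = 3 (p + 1) / n

(p predictors, n training compounds) marks the boundary.  The Williams
plot displays standardized residuals against leverages; points beyond h*
are structurally influential, points outside the residual band (default
+/-3 standardized units) are response outliers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .qsar import QSARResults

__all__ = [
    "warning_leverage",
    "leverages",
    "standardized_residuals",
    "williams_data",
]


def warning_leverage(n: int, p: int) -> float:
    """Warning leverage h* = 3(p+1)/n for n samples and p predictors."""
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if p < 1:
        raise ValidationError(f"p must be at least 1, got {p}")
    return 3.0 * (p + 1) / n


def leverages(results: QSARResults) -> np.ndarray:
    """Hat-matrix diagonal of the intercept-augmented training design.

    Sums to p+1 (the trace of the hat matrix equals the number of fitted
    parameters) and each value lies in [1/n, 1] for an intercept model.
    """
    return results.leverages.copy()


def standardized_residuals(results: QSARResults, kind: str = "simple") -> np.ndarray:
    """Residuals scaled to unit spread.

    kind="simple" (default): e_i / s with s = sqrt(RSS/(n-p-1)).
    kind="internal": internally studentized, e_i / (s * sqrt(1-h_i)).
    """
    if results.df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    s = np.sqrt(results.mse)
    if results.ss_resid <= 1e-14 * max(results.ss_total, np.finfo(float).tiny):
        raise ValidationError("perfect fit: standardized residuals undefined")
    if kind == "simple":
        return results.resid / s
    if kind == "internal":
        return results.resid / (s * np.sqrt(1.0 - results.leverages))
    raise ValidationError(f"unknown standardization kind {kind!r}")


def williams_data(
    results: QSARResults,
    residual_cutoff: float = 3.0,
    kind: str = "simple",
) -> pd.DataFrame:
    """Per-compound applicability-domain records for a Williams plot.

    Returns a frame with columns ``compound_id``, ``leverage``,
    ``resid_std``, ``h_star``, ``high_leverage`` (h_i > h*) and
    ``outlier`` (|r_i| > residual_cutoff).
    """
    h = leverages(results)
    r = standardized_residuals(results, kind=kind)
    h_star = warning_leverage(results.nobs, results.n_predictors)
    return pd.DataFrame(
        {
            "compound_id": results.model.compound_ids,
            "leverage": h,
            "resid_std": r,
            "h_star": h_star,
            "high_leverage": h > h_star,
            "outlier": np.abs(r) > residual_cutoff,
        }
    )
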