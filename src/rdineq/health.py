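"""Comprehensive health index.

Survey health status comes as two ordinal ratings on different scales: a
self-rated score (1-5, "unhealthy" .. "very healthy") and a score rated
by the interviewer (1-7, "very poor" .. "very good"). Because the scales
differ, each rating is z-standardized and the two z-scores are summed to
form a single continuous health index used as the outcome everywhere
downstream.

Standardization uses the population convention (divisor ``n``) and is
always computed on the full input sample, so that subgroup analyses stay
on a common scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["standardize", "composite_health"]


def standardize(values) -> np.ndarray:
    """Return z-scores with mean 0 and population standard deviation 1.

    Raises
    ------
    ValueError
        If fewer than two values are supplied or the sample is constant
        (a constant rating carries no information to standardize).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a one-dimensional vector")
    if x.size < 2:
        raise ValueError(f"standardize needs n >= 2 values, got n={x.size}")
    sd = x.std()  # population convention, divisor n
    if sd == 0:
        raise ValueError(
            "zero variance: all values are identical; a constant rating "
            "cannot be standardized"
        )
    return (x - x.mean()) / sd


def composite_health(self_health, other_health) -> np.ndarray:
    """Sum of the z-scores of the two ordinal health ratings.

    Both vectors are standardized on the sample supplied here; the
    result has mean 0 on that sample by construction.
    """
    a = np.asarray(self_health, dtype=float)
    b = np.asarray(other_health, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"rating vectors must have the same length, got {a.shape} and {b.shape}"
        )
    return standardize(a) + standardize(b)


def add_composite_health(cohort: pd.DataFrame, column: str = "health") -> pd.DataFrame:
    """Return a copy of ``cohort`` with the composite index as ``column``."""
    out = cohort.copy()
    out[column] = composite_health(cohort["self_health"], cohort["other_health"])
    return out
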