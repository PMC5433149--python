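"""Normalization and filtering applied before genome-wide analyses.

Quantile normalization forces every sample (column) to share one empirical
distribution; the variance filter removes low-information probes before any
global analysis; beta -> M converts methylation fractions to the log2-odds
scale that behaves better in differential testing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["quantile_normalize", "variance_filter", "beta_to_m", "m_to_beta"]

M_CLAMP_EPS = 1e-6


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalize columns so all samples share one distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values. Ties within a column receive the mean of the target values
    over their rank span ("average ties" dialect), which makes the transform
    idempotent.
    """
    values = x.values
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quantile_normalize: input contains NaN")
    if arr.shape[1] < 2:
        raise ValueError("quantile_normalize: need at least 2 samples")

    order = np.argsort(arr, axis=0, kind="stable")
    target = np.sort(arr, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        assigned = target.copy()
        # average target values over each tie span
        start = 0
        for k in range(1, len(sorted_col) + 1):
            if k == len(sorted_col) or sorted_col[k] != sorted_col[start]:
                if k - start > 1:
                    assigned[start:k] = target[start:k].mean()
                start = k
        out[idx, j] = assigned

    return ExpressionMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns), normalized=True
    )


def variance_filter(x: ExpressionMatrix, drop_fraction: float) -> ExpressionMatrix:
    """Drop the ``floor(drop_fraction * n_features)`` lowest-variance features.

    Sample variance (n-1 denominator); ties in variance are broken by feature
    id lexicographic order so the result is deterministic.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    values = x.values
    n_drop = int(np.floor(drop_fraction * values.shape[0]))
    if n_drop == 0:
        return ExpressionMatrix(values.copy(), x.normalized)
    var = values.var(axis=1, ddof=1)
    order = sorted(values.index, key=lambda f: (var[f], f))
    keep = set(order[n_drop:])
    kept = values.loc[[f for f in values.index if f in keep]]
    return ExpressionMatrix(kept, x.normalized)


def beta_to_m(beta) -> pd.DataFrame:
    """M-value transform M = log2(beta / (1 - beta)).

    Values in [0, eps] or [1-eps, 1] are clamped to avoid infinities; the
    clamp count is reported as a warning. Values outside [0, 1] are an error.
    """
    df = pd.DataFrame(beta)
    arr = df.to_numpy(dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("beta values must lie in [0, 1]")
    n_clamped = int(np.sum((arr < M_CLAMP_EPS) | (arr > 1 - M_CLAMP_EPS)))
    if n_clamped:
        warnings.warn(f"beta_to_m: clamped {n_clamped} values to ({M_CLAMP_EPS}, {1 - M_CLAMP_EPS})")
    clamped = np.clip(arr, M_CLAMP_EPS, 1 - M_CLAMP_EPS)
    m = np.log2(clamped / (1 - clamped))
    return pd.DataFrame(m, index=df.index, columns=df.columns)


def m_to_beta(m) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` on the unclamped range."""
    df = pd.DataFrame(m)
    arr = df.to_numpy(dtype=float)
    beta = 1.0 / (1.0 + np.power(2.0, -arr))
    return pd.DataFrame(beta, index=df.index, columns=df.columns)
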