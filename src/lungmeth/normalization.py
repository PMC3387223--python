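"""Between-array quantile normalization on the beta scale.

Forces every array (column) to share the same empirical distribution — the
rank-wise mean of the column-sorted values — while preserving within-column
ranks. Tied input values receive the mean of their tied target quantiles,
which makes the map deterministic and stable under sample permutation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataio import ValidationError

__all__ = ["quantile_normalize", "beta_to_m", "m_to_beta"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a probes x samples matrix across columns.

    With a single column the input is returned unchanged (with a warning);
    missing values are rejected — impute or drop before normalizing.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).all(axis=0).any():
        raise ValidationError("all-missing column", code="missing")
    if np.isnan(values).any():
        raise ValidationError(
            "missing values present; impute or drop before normalization",
            code="missing",
        )
    if matrix.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is a no-op", stacklevel=2)
        return matrix.copy()

    order = np.argsort(values, axis=0, kind="stable")
    target = np.mean(np.take_along_axis(values, order, axis=0), axis=1)

    out = np.empty_like(values)
    cum = np.concatenate([[0.0], np.cumsum(target)])
    for j in range(values.shape[1]):
        col_sorted = values[order[:, j], j]
        # boundaries of runs of tied values in sorted order
        change = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(col_sorted)]])
        run_means = (cum[ends] - cum[starts]) / (ends - starts)
        run_id = np.zeros(len(col_sorted), dtype=int)
        run_id[starts[1:]] = 1
        run_id = np.cumsum(run_id)
        out[order[:, j], j] = run_means[run_id]
    # rank-wise means are bounded by the input range; clip float drift from
    # the cumulative sums
    np.clip(out, values.min(), values.max(), out=out)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def beta_to_m(beta: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """Optional logit (M-value) transform: M = log2(beta / (1 - beta))."""
    b = beta.clip(lower=eps, upper=1 - eps)
    return np.log2(b / (1 - b))


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    e = np.exp2(m)
    return e / (1 + e)
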