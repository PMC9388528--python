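"""Benjamini-Hochberg FDR adjustment and PRS risk-group assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bh_fdr", "assign_risk_groups"]


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with family size ``m``.

    ``m`` defaults to the number of p-values but may be fixed larger — a
    study testing a family of m comparisons can adjust any subset against
    the full family denominator.  Adjusted value i is
    ``min_{j >= i} p_(j) * m / j`` over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of tests {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


def assign_risk_groups(prs_z) -> pd.Series:
    """Classify z-standardized PRS into low / medium / high risk groups.

    low: z < -1; high: z > 1; medium otherwise — the boundary values
    z = +-1 fall in the medium group (closed interval).
    """
    z = np.asarray(prs_z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("PRS z-scores must be finite")
    labels = np.where(z < -1.0, "low", np.where(z > 1.0, "high", "medium"))
    index = prs_z.index if isinstance(prs_z, pd.Series) else None
    return pd.Series(
        pd.Categorical(labels, categories=["low", "medium", "high"]),
        index=index,
        name="risk_group",
    )
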