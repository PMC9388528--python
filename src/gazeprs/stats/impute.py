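"""Predictive mean matching (PMM) for missing covariates.

Each incomplete covariate is regressed on the complete covariates; every
missing case is matched to the donor pool of the k observed cases whose
model-predicted values are nearest to the missing case's prediction, and
inherits one donor's *observed* value.  The regression is refitted on
bootstrap resamples (default 10) to propagate parameter uncertainty, and
the final imputation is drawn from the pooled donors across resamples.
By construction imputed values always lie in the observed support.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pmm_impute"]


def pmm_impute(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    n_boot: int = 10,
    k_donors: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Complete ``table`` by predictive mean matching on ``columns``.

    ``columns`` defaults to every numeric column containing missing values.
    Predictors are the numeric columns with no missing values.  Raises if a
    target column is entirely missing or no complete predictor exists.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    numeric = [c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])]
    if columns is None:
        columns = [c for c in numeric if out[c].isna().any()]
    if not columns:
        return out
    predictors = [c for c in numeric if not out[c].isna().any()]
    if not predictors:
        raise ValueError("no complete numeric predictor columns available")

    Xfull = np.column_stack(
        [np.ones(len(out))] + [out[c].to_numpy(dtype=float) for c in predictors]
    )
    for col in columns:
        y = out[col].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if not obs.any():
            raise ValueError(f"covariate {col!r} has no observed values")
        mis = ~obs
        if not mis.any():
            continue
        X_obs, y_obs = Xfull[obs], y[obs]
        X_mis = Xfull[mis]
        pooled = [[] for _ in range(int(mis.sum()))]
        n_obs = len(y_obs)
        for _ in range(n_boot):
            idx = rng.integers(0, n_obs, n_obs)
            coef, *_ = np.linalg.lstsq(X_obs[idx], y_obs[idx], rcond=None)
            pred_obs = X_obs @ coef  # donors scored with the resampled model
            pred_mis = X_mis @ coef
            for i, pm in enumerate(pred_mis):
                nearest = np.argsort(np.abs(pred_obs - pm))[:k_donors]
                pooled[i].extend(y_obs[nearest])
        imputed = np.array([rng.choice(p) for p in pooled])
        y[mis] = imputed
        out[col] = y
    return out
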