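"""Linear association models, gene-age interaction tests and slope contrasts.

The canonical association model regresses one cognitive outcome on a
z-standardized polygenic risk score, adjusting for mean-centred age, its
square, sex and the first six genetic principal components:

    outcome ~ b0 + b1*PRS_z + age_c + age_c^2 + sex + PC1..PC6 + error

Age is centred before squaring to reduce collinearity between the linear
and quadratic terms.  Heavily skewed outcomes are natural-log transformed
before fitting.  The interaction model adds PRS_z x age_c and
PRS_z x age_c^2 and is compared against the base model with a nested-model
F test (2 numerator df); the asymptotic chi-squared likelihood-ratio
statistic is reported alongside, since for Gaussian linear models the two
are monotone transforms of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LOG_TRANSFORM_OUTCOMES",
    "ModelSpec",
    "AssociationResult",
    "InteractionTestResult",
    "build_design",
    "fit_linear_model",
    "test_interaction",
    "tukey_slope_contrasts",
]

#: Outcomes fitted on the natural-log scale (right-skewed in cohort data):
#: the two trail-making completion times, pro/antisaccade spatial error and
#: the three fixation-stability measures.
LOG_TRANSFORM_OUTCOMES = (
    "tmt_a",
    "tmt_b",
    "prosaccade_spatial_error",
    "antisaccade_spatial_error",
    "fixation_spatial_error",
    "fixation_saccade_rate",
    "fixation_blink_rate",
)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one outcome-on-PRS association model."""

    outcome: str
    predictor: str = "prs_z"
    log_transform: bool = False
    age_col: str = "age"
    sex_col: str = "sex"
    pc_cols: tuple[str, ...] = ("PC1", "PC2", "PC3", "PC4", "PC5", "PC6")
    interaction: bool = False

    @classmethod
    def for_outcome(cls, outcome: str, **kwargs) -> "ModelSpec":
        return cls(
            outcome=outcome,
            log_transform=outcome in LOG_TRANSFORM_OUTCOMES,
            **kwargs,
        )


@dataclass
class AssociationResult:
    """One row of an association table: one PRS against one outcome."""

    outcome: str
    b: float
    ci95: tuple[float, float]
    p_raw: float
    n_used: int
    p_fdr: float | None = None

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "b": self.b,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "n": self.n_used,
        }


@dataclass
class InteractionTestResult:
    """Nested-model comparison for PRS x age and PRS x age^2 terms."""

    outcome: str
    f_value: float
    df: tuple[int, int]
    p_raw: float
    lr_chi2: float
    p_lrt: float
    p_fdr: float | None = None


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    """Response vector and design matrix for ``spec`` on complete rows.

    Age is centred at the analysis-sample mean before squaring; interaction
    columns (if requested) multiply the PRS by centred age and its square.
    """
    cols = [spec.outcome, spec.predictor, spec.age_col, spec.sex_col, *spec.pc_cols]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    df = data[cols].dropna()
    y = df[spec.outcome].astype(float)
    if spec.log_transform:
        if (y <= 0).any():
            raise ValueError(
                f"log transform requested for {spec.outcome!r} but outcome "
                "has non-positive values"
            )
        y = np.log(y)
    age_c = df[spec.age_col] - df[spec.age_col].mean()
    X = pd.DataFrame(
        {
            "const": 1.0,
            spec.predictor: df[spec.predictor].astype(float),
            "age_c": age_c,
            "age_c2": age_c**2,
            "sex": df[spec.sex_col].astype(float),
        },
        index=df.index,
    )
    for pc in spec.pc_cols:
        X[pc] = df[pc].astype(float)
    if spec.interaction:
        X["prs_x_age"] = X[spec.predictor] * X["age_c"]
        X["prs_x_age2"] = X[spec.predictor] * X["age_c2"]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return y, X


def fit_linear_model(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[AssociationResult, pd.DataFrame]:
    """OLS fit of the association model; returns the PRS row and full table.

    Standard errors use the usual unbiased residual-variance estimate;
    p-values and 95% CIs are two-sided t-based.
    """
    y, X = build_design(data, spec)
    if len(y) <= X.shape[1] + 2:
        raise ValueError(f"too few complete rows (n={len(y)}) for the design")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    pred = spec.predictor
    result = AssociationResult(
        outcome=spec.outcome,
        b=float(fit.params[pred]),
        ci95=(float(ci.loc[pred, 0]), float(ci.loc[pred, 1])),
        p_raw=float(fit.pvalues[pred]),
        n_used=int(fit.nobs),
    )
    return result, table


def test_interaction(data: pd.DataFrame, spec: ModelSpec) -> InteractionTestResult:
    """F test (2 df) of adding PRS x age and PRS x age^2 to the base model.

    Both models are fitted on the identical complete-case rows.  Reports the
    nested-model F statistic ((RSS0 - RSS1)/2) / (RSS1/df_res) and the
    asymptotic chi-squared LRT n*log(RSS0/RSS1) alongside.
    """
    base_spec = ModelSpec(**{**spec.__dict__, "interaction": False})
    ext_spec = ModelSpec(**{**spec.__dict__, "interaction": True})
    y0, X0 = build_design(data, base_spec)
    y1, X1 = build_design(data, ext_spec)
    if not y0.index.equals(y1.index):
        raise ValueError("base and extended models use differing case sets")
    added = [c for c in X1.columns if c not in X0.columns]
    if not added or any(X1[c].std() == 0 for c in added):
        raise ValueError("interaction terms are degenerate (zero variance)")
    fit0 = sm.OLS(y0, X0).fit()
    fit1 = sm.OLS(y1, X1).fit()
    rss0, rss1 = float(fit0.ssr), float(fit1.ssr)
    df1 = len(added)
    df2 = int(fit1.df_resid)
    f_value = ((rss0 - rss1) / df1) / (rss1 / df2)
    p_f = float(stats.f.sf(f_value, df1, df2))
    n = len(y0)
    lr = n * np.log(rss0 / rss1)
    p_lr = float(stats.chi2.sf(lr, df1))
    return InteractionTestResult(
        outcome=spec.outcome,
        f_value=float(f_value),
        df=(df1, df2),
        p_raw=p_f,
        lr_chi2=float(lr),
        p_lrt=p_lr,
    )


def tukey_slope_contrasts(
    data: pd.DataFrame,
    groups: pd.Series,
    outcome: str,
    age_col: str = "age",
) -> pd.DataFrame:
    """Tukey-adjusted pairwise differences of group-specific age trends.

    Fits ``outcome ~ group * (age_c + age_c^2)`` and compares the marginal
    linear age trend of each risk group — the derivative of the fitted
    curve with respect to age averaged over the observed ages, which with
    centred age reduces to the group's linear age coefficient.  Pairwise
    differences are referred to the studentized-range distribution with
    k = 3 groups (familywise-adjusted p-values).
    """
    df = pd.DataFrame(
        {"y": data[outcome].astype(float), "age": data[age_col].astype(float)}
    )
    df["group"] = np.asarray(groups)
    df = df.dropna()
    levels = ["low", "medium", "high"]
    counts = df["group"].value_counts()
    for lv in levels:
        if counts.get(lv, 0) < 3:
            raise ValueError(f"risk group {lv!r} has fewer than 3 subjects")
    age_c = df["age"] - df["age"].mean()
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    slope_cols = {}
    for lv in levels:
        ind = (df["group"] == lv).astype(float)
        if lv != levels[0]:
            X[f"g_{lv}"] = ind
        X[f"age_{lv}"] = ind * age_c
        X[f"age2_{lv}"] = ind * age_c**2
        slope_cols[lv] = f"age_{lv}"
    fit = sm.OLS(df["y"], X).fit()
    params, cov = fit.params, fit.cov_params()
    k = len(levels)
    dfr = int(fit.df_resid)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = slope_cols[levels[i]], slope_cols[levels[j]]
            diff = float(params[a] - params[b])
            se = float(np.sqrt(cov.loc[a, a] + cov.loc[b, b] - 2 * cov.loc[a, b]))
            if se == 0:
                p_adj = 1.0
            else:
                q = abs(diff) / se * np.sqrt(2.0)
                p_adj = float(stats.studentized_range.sf(q, k, dfr))
            rows.append(
                {
                    "contrast": f"{levels[i]} - {levels[j]}",
                    "estimate": diff,
                    "se": se,
                    "p_tukey": min(1.0, p_adj),
                }
            )
    return pd.DataFrame(rows)
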