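"""Analytic power for the fixed-predictor F-test in multiple regression.

Power is computed for the test of a single additional predictor (numerator
degrees of freedom ``df1``) in a linear model, parameterised by Cohen's
f-squared — the increment in explained variance divided by the unexplained
variance.  Under the alternative the test statistic follows a noncentral F
distribution with noncentrality ``lambda = f2 * n`` (the fixed-model
R-squared-increase convention), numerator df ``df1`` and denominator df
``n - df1 - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats

__all__ = ["PowerQuery", "power_f_test", "detectable_effect"]


@dataclass(frozen=True)
class PowerQuery:
    """One power computation: effect size, sample size, alpha, numerator df."""

    f2: float
    n: int
    alpha: float = 0.05
    df1: int = 1

    def __post_init__(self) -> None:
        if self.f2 < 0:
            raise ValueError(f"f2 must be >= 0, got {self.f2}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.df1 < 1:
            raise ValueError(f"df1 must be >= 1, got {self.df1}")
        if self.n <= self.df1 + 1:
            raise ValueError(
                f"n must exceed df1 + 1 = {self.df1 + 1}, got {self.n}"
            )


def power_f_test(query: PowerQuery) -> float:
    """Power of the F-test for ``df1`` predictors at effect size ``f2``.

    Returns P(F' > F_crit) where F' is noncentral F with noncentrality
    ``f2 * n`` and F_crit the central-F ``1 - alpha`` quantile.  At f2 = 0
    the power equals alpha (the size of the test).
    """
    df2 = query.n - query.df1 - 1
    crit = stats.f.ppf(1.0 - query.alpha, query.df1, df2)
    lam = query.f2 * query.n
    if lam == 0.0:
        return float(stats.f.sf(crit, query.df1, df2))
    return float(stats.ncf.sf(crit, query.df1, df2, lam))


def detectable_effect(
    target_power: float, n: int, alpha: float = 0.05, df1: int = 1
) -> float:
    """Smallest Cohen's f2 detectable with ``target_power`` at size ``alpha``.

    Inverts :func:`power_f_test` by bracketed root search; tolerance 1e-8
    on f2.  Raises ``ValueError`` when ``target_power`` is not strictly
    between ``alpha`` (the power at f2 = 0) and 1.
    """
    if not alpha < target_power < 1:
        raise ValueError(
            f"target power must lie in ({alpha}, 1), got {target_power}"
        )

    def gap(f2: float) -> float:
        return power_f_test(PowerQuery(f2, n, alpha, df1)) - target_power

    hi = 1.0 / n
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("failed to bracket detectable effect size")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-8))
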