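"""One-inflated beta regression by maximum likelihood.

A bounded outcome with a point mass at exactly 1 — e.g. the antisaccade
correction rate, where most subjects correct every direction error — is
modelled as a two-part mixture:

* a logistic component for the probability that the outcome equals 1,
  P(y = 1 | x) = sigmoid(x'gamma);
* a beta component for outcomes strictly inside (0, 1), with mean
  mu = sigmoid(x'beta) and precision phi, i.e. y ~ Beta(mu*phi, (1-mu)*phi).

The joint log-likelihood factorizes over the two parts, so the joint
maximum coincides with maximizing each part separately; the model is
nevertheless fitted as one joint optimization and the factorization is an
invariant checked in the test suite.  Effects of a predictor on the
one-inflation probability are reported as odds ratios with Wald intervals.

The API follows the statsmodels Model/Results convention:
``OneInflatedBeta(endog, exog).fit()`` returns a results object carrying
``params``, ``bse``, ``conf_int()`` and ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = ["OneInflatedBeta", "OneInflatedBetaResults"]

_SIG_CLIP = 500.0


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return special.expit(np.clip(eta, -_SIG_CLIP, _SIG_CLIP))


def _mean_clip(mu: np.ndarray) -> np.ndarray:
    # keep the beta mean strictly inside (0, 1) so digamma stays finite
    # during line searches through extreme parameter values
    return np.clip(mu, 1e-12, 1.0 - 1e-12)


class OneInflatedBeta:
    """One-inflated beta regression model for an outcome in (0, 1].

    Parameters
    ----------
    endog : array-like
        Outcome values, each in (0, 1]; at least one value must equal 1 and
        at least one must be below 1.
    exog : array-like or DataFrame
        Design matrix shared by both mixture components (include a constant
        column explicitly).
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
            self.exog_names = [f"x{i}" for i in range(self.exog.shape[1])]
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if np.any((self.endog <= 0) | (self.endog > 1)):
            raise ValueError("outcome values must lie in (0, 1]")
        self._one = self.endog == 1.0
        if self._one.all():
            raise ValueError("all outcomes equal 1: beta component is empty")
        if not self._one.any():
            raise ValueError(
                "no outcome equals 1: fit a plain beta regression instead"
            )
        self.k = self.exog.shape[1]
        self.param_names = (
            [f"logit_{n}" for n in self.exog_names]
            + [f"beta_{n}" for n in self.exog_names]
            + ["log_phi"]
        )

    # -- likelihood -------------------------------------------------------

    def _unpack(self, params):
        k = self.k
        return params[:k], params[k : 2 * k], params[2 * k]

    def loglike(self, params) -> float:
        gamma, beta, log_phi = self._unpack(np.asarray(params, dtype=float))
        phi = np.exp(log_phi)
        eta1 = self.exog @ gamma
        # logistic part over all observations
        ll = np.sum(np.where(self._one, -np.logaddexp(0, -eta1), -np.logaddexp(0, eta1)))
        y = self.endog[~self._one]
        x = self.exog[~self._one]
        mu = _mean_clip(_sigmoid(x @ beta))
        a, b = mu * phi, (1.0 - mu) * phi
        ll += np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
        return float(ll)

    def score(self, params) -> np.ndarray:
        gamma, beta, log_phi = self._unpack(np.asarray(params, dtype=float))
        phi = np.exp(log_phi)
        s = _sigmoid(self.exog @ gamma)
        g_gamma = self.exog.T @ (self._one.astype(float) - s)
        y = self.endog[~self._one]
        x = self.exog[~self._one]
        mu = _mean_clip(_sigmoid(x @ beta))
        a, b = mu * phi, (1.0 - mu) * phi
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(a) - special.digamma(b)
        g_beta = x.T @ (phi * mu * (1.0 - mu) * (ystar - mustar))
        d_phi = np.sum(
            special.digamma(phi)
            - mu * special.digamma(a)
            - (1.0 - mu) * special.digamma(b)
            + mu * np.log(y)
            + (1.0 - mu) * np.log1p(-y)
        )
        return np.concatenate([g_gamma, g_beta, [d_phi * phi]])

    def _start_params(self) -> np.ndarray:
        p1 = float(np.mean(self._one))
        gamma0 = np.zeros(self.k)
        beta0 = np.zeros(self.k)
        const_idx = next(
            (i for i, n in enumerate(self.exog_names) if n in ("const", "Intercept")),
            0,
        )
        gamma0[const_idx] = special.logit(np.clip(p1, 1e-3, 1 - 1e-3))
        y = self.endog[~self._one]
        mbar = float(np.clip(np.mean(y), 1e-3, 1 - 1e-3))
        v = max(float(np.var(y)), 1e-6)
        phi0 = max(mbar * (1.0 - mbar) / v - 1.0, 0.5)
        beta0[const_idx] = special.logit(mbar)
        return np.concatenate([gamma0, beta0, [np.log(phi0)]])

    def fit(self, maxiter: int = 500, gtol: float = 1e-8) -> "OneInflatedBetaResults":
        """Joint maximum likelihood via quasi-Newton (BFGS) with analytic score."""
        x0 = self._start_params()
        res = optimize.minimize(
            lambda p: -self.loglike(p),
            x0,
            jac=lambda p: -self.score(p),
            method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        params = res.x
        hess = approx_hess(params, self.loglike)
        try:
            cov = np.linalg.inv(-hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.full((len(params), len(params)), np.nan)
            bse = np.full(len(params), np.nan)
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4
        return OneInflatedBetaResults(
            model=self,
            params=params,
            bse=bse,
            cov_params=cov,
            llf=float(self.loglike(params)),
            converged=converged,
        )


class OneInflatedBetaResults:
    """Fitted one-inflated beta regression: estimates, SEs and summaries."""

    def __init__(self, model, params, bse, cov_params, llf, converged):
        self.model = model
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.cov_params = cov_params
        self.llf = llf
        self.converged = converged
        k = model.k
        self.gamma = pd.Series(self.params[:k], index=model.exog_names)
        self.beta = pd.Series(self.params[k : 2 * k], index=model.exog_names)
        self.phi = float(np.exp(self.params[2 * k]))
        self.gamma_bse = pd.Series(self.bse[:k], index=model.exog_names)
        self.beta_bse = pd.Series(self.bse[k : 2 * k], index=model.exog_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "low": self.params - z * self.bse,
                "high": self.params + z * self.bse,
            },
            index=self.model.param_names,
        )

    def one_inflation_probability(self, exog=None) -> np.ndarray:
        """Fitted P(outcome = 1) for each row of ``exog`` (default: fit data)."""
        x = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return _sigmoid(x @ self.gamma.to_numpy())

    def odds_ratio(self, name: str, alpha: float = 0.05) -> dict:
        """Odds ratio (per unit of predictor ``name``) for P(outcome = 1).

        A ratio below 1 means higher predictor values lower the odds of the
        outcome sitting exactly at 1 (e.g. of correcting every error).
        """
        g = float(self.gamma[name])
        se = float(self.gamma_bse[name])
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        p = 2.0 * stats.norm.sf(abs(g) / se) if se > 0 else np.nan
        return {
            "or": float(np.exp(g)),
            "ci_low": float(np.exp(g - z * se)),
            "ci_high": float(np.exp(g + z * se)),
            "p": float(p),
        }

    def beta_part_odds_ratio_complement(self, name: str, alpha: float = 0.05) -> dict:
        """Beta-part effect expressed on the complement scale (1 - y).

        The beta component models the mean of y on the logit scale; for an
        outcome like "fraction of errors corrected" the complementary
        "fraction left uncorrected" has logit-mean with all coefficients
        sign-flipped, so the reported ratio is exp(-beta_name).
        """
        b = float(self.beta[name])
        se = float(self.beta_bse[name])
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan
        return {
            "or": float(np.exp(-b)),
            "ci_low": float(np.exp(-b - z * se)),
            "ci_high": float(np.exp(-b + z * se)),
            "p": float(p),
        }

    def summary(self) -> str:
        lines = [
            "One-inflated beta regression",
            f"  n = {len(self.model.endog)}  "
            f"(at 1: {int(self.model._one.sum())}, in (0,1): "
            f"{int((~self.model._one).sum())})",
            f"  log-likelihood = {self.llf:.4f}   converged = {self.converged}",
            f"  precision phi = {self.phi:.4f}",
            "",
            f"  {'component':<10}{'term':<14}{'coef':>10}{'se':>10}{'exp(coef)':>11}",
        ]
        for comp, co, se in (
            ("logistic", self.gamma, self.gamma_bse),
            ("beta", self.beta, self.beta_bse),
        ):
            for nm in co.index:
                lines.append(
                    f"  {comp:<10}{nm:<14}{co[nm]:>10.4f}{se[nm]:>10.4f}"
                    f"{np.exp(co[nm]):>11.4f}"
                )
        return "\n".join(lines)
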