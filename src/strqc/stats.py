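"""Statistical engines for STR association testing.

The workhorse is Firth's bias-reduced logistic regression: carrier counts at
pathogenic thresholds are tiny and often separated (e.g. zero expanded
controls), and the Jeffreys-prior penalty ``l(b) + 0.5 log det I(b)``
guarantees finite estimates there.  The model class / results object pair
follows the statsmodels convention.

Survival modifiers are fitted with Cox proportional hazards (Efron ties,
via lifelines), age-at-onset modifiers with ordinary least squares.
Multiple-testing helpers implement Benjamini-Hochberg FDR and Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

ODDS_RATIO = "odds_ratio"
HAZARD_RATIO = "hazard_ratio"
IDENTITY = "identity"

_Z95 = sps.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """A likelihood maximization failed to converge."""


@dataclass
class RegressionFit:
    """Estimates, uncertainties and Wald inference for one fitted model.

    ``coefficients`` are on the linear-predictor scale; ``ci_low``/``ci_high``
    and :meth:`effects` are on the effect scale (odds ratio, hazard ratio, or
    identity).
    """

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    effect_scale: str
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_obs: int
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def effects(self) -> np.ndarray:
        if self.effect_scale in (ODDS_RATIO, HAZARD_RATIO):
            return np.exp(self.coefficients)
        return self.coefficients.copy()

    def summary(self) -> pd.DataFrame:
        label = {ODDS_RATIO: "OR", HAZARD_RATIO: "HR", IDENTITY: "coef"}[self.effect_scale]
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coefficients,
                "se": self.standard_errors,
                label: self.effects(),
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": self.coefficients[i],
            "se": self.standard_errors[i],
            "effect": self.effects()[i],
            "ci_low": self.ci_low[i],
            "ci_high": self.ci_high[i],
            "p": self.p_values[i],
        }


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR on the gram matrix
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * max(diag.max(), 1.0))[0]]
        raise np.linalg.LinAlgError(f"design matrix is rank deficient (collinear columns: {bad or 'unknown'})")


def _wald(names, beta, se, effect_scale, n_obs, converged=True, extras=None) -> RegressionFit:
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    lo = beta - _Z95 * se
    hi = beta + _Z95 * se
    if effect_scale in (ODDS_RATIO, HAZARD_RATIO):
        lo, hi = np.exp(np.clip(lo, -700, 700)), np.exp(np.clip(hi, -700, 700))
    return RegressionFit(
        names=list(names),
        coefficients=np.asarray(beta, float),
        standard_errors=np.asarray(se, float),
        p_values=p,
        effect_scale=effect_scale,
        ci_low=lo,
        ci_high=hi,
        n_obs=n_obs,
        converged=converged,
        extras=extras or {},
    )


# ---------------------------------------------------------------------------
# Firth penalized logistic regression
# ---------------------------------------------------------------------------


class FirthLogit:
    """Firth bias-reduced logistic regression model.

    Parameters
    ----------
    endog : binary outcome vector (1 = event).
    exog : design matrix including the intercept column.
    names : column names for the summary (optional).
    """

    def __init__(self, endog, exog, names: Sequence[str] | None = None):
        self.endog = np.asarray(endog, float).ravel()
        self.exog = np.asarray(exog, float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        n, p = self.exog.shape
        if self.endog.shape[0] != n:
            raise ValueError("endog and exog lengths differ")
        if n < p:
            raise ValueError("need at least as many observations as parameters")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")
        self.names = list(names) if names is not None else [f"x{i}" for i in range(p)]
        _check_full_rank(self.exog, self.names)

    def penalized_loglik(self, beta: np.ndarray) -> float:
        eta = self.exog @ beta
        ll = float(self.endog @ eta - np.logaddexp(0.0, eta).sum())
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        sign, logdet = np.linalg.slogdet(self.exog.T * w @ self.exog)
        return ll + 0.5 * logdet

    def _score_info(self, beta: np.ndarray):
        X = self.exog
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = X.T * w @ X
        a = np.linalg.solve(info, X.T)  # p x n
        h = w * np.einsum("ij,ji->i", X, a)
        score = X.T @ (self.endog - p + h * (0.5 - p))
        return score, info

    def fit(self, maxiter: int = 100, tol: float = 1e-9) -> "FirthLogitResults":
        beta = np.zeros(self.exog.shape[1])
        ll = self.penalized_loglik(beta)
        for _ in range(maxiter):
            score, info = self._score_info(beta)
            if np.max(np.abs(score)) < tol:
                break
            step = np.linalg.solve(info, score)
            # step-halving keeps the penalized likelihood non-decreasing; the
            # tolerance must stay below the cycle amplitude of an overshooting
            # Newton step but above floating-point noise near the optimum
            accepted = False
            slack = 1e-13 * max(1.0, abs(ll))
            for _ in range(50):
                candidate = beta + step
                cand_ll = self.penalized_loglik(candidate)
                if cand_ll >= ll - slack:
                    accepted = True
                    break
                step = step / 2.0
            if not accepted:
                break  # no improving step at floating-point resolution
            beta = candidate
            ll = cand_ll
        score, info = self._score_info(beta)
        converged = bool(np.max(np.abs(score)) < max(tol, 1e-7))
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        return FirthLogitResults(self, beta, se, cov, ll, converged)


class FirthLogitResults:
    """Results of a :class:`FirthLogit` fit, with Wald inference."""

    def __init__(self, model, params, bse, cov, llf, converged):
        self.model = model
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.cov_params = cov
        self.llf = llf  # penalized log-likelihood at the optimum
        self.converged = converged

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * sps.norm.sf(np.abs(z))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = sps.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, float)
        return expit(X @ self.params)

    def summary(self) -> pd.DataFrame:
        return self.as_fit().summary()

    def as_fit(self) -> RegressionFit:
        return _wald(
            self.model.names,
            self.params,
            self.bse,
            ODDS_RATIO,
            len(self.model.endog),
            self.converged,
            extras={"llf": self.llf},
        )


def firth_logistic(design, outcome, names: Sequence[str] | None = None) -> RegressionFit:
    """Fit Firth logistic regression; design must include the intercept column."""
    return FirthLogit(outcome, design, names).fit().as_fit()


# ---------------------------------------------------------------------------
# Cox proportional hazards (lifelines backend, Efron ties)
# ---------------------------------------------------------------------------


def cox_ph(time, event, design, names: Sequence[str] | None = None) -> RegressionFit:
    """Cox proportional-hazards fit via the partial likelihood (Efron ties).

    ``design`` must NOT include an intercept (the baseline hazard absorbs it).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LLConvergenceError

    time = np.asarray(time, float).ravel()
    event = np.asarray(event).astype(int).ravel()
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError("no events observed; Cox model is not identified")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_full_rank(X, names)
    df = pd.DataFrame(X, columns=names)
    df["_time"] = time
    df["_event"] = event
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"precision": 1e-10, "max_steps": 500},
            )
    except (LLConvergenceError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(
            "Cox partial likelihood did not converge (monotone likelihood / separation "
            f"is the usual cause): {exc}"
        ) from exc
    beta = fitter.params_.to_numpy()
    se = fitter.standard_errors_.to_numpy()
    fit = _wald(names, beta, se, HAZARD_RATIO, len(time))
    fit.extras["fitter"] = fitter
    fit.extras["data"] = df
    return fit


def schoenfeld_ph_check(fit: RegressionFit) -> pd.Series:
    """Proportional-hazards check: scaled Schoenfeld residuals vs event-time rank.

    Returns a per-covariate p-value Series (NaN = untestable: fewer than three
    events or a constant covariate).
    """
    from lifelines.statistics import proportional_hazard_test

    fitter = fit.extras.get("fitter")
    df = fit.extras.get("data")
    if fitter is None or df is None:
        raise ValueError("fit does not carry its lifelines fitter; refit with cox_ph")
    out = pd.Series(np.nan, index=fit.names, dtype=float)
    if int(df["_event"].sum()) < 3:
        return out
    testable = [c for c in fit.names if df[c].nunique() > 1]
    if not testable:
        return out
    res = proportional_hazard_test(fitter, df, time_transform="rank")
    pvals = res.summary["p"]
    for name in testable:
        if name in pvals.index:
            out[name] = float(pvals.loc[name])
    return out


# ---------------------------------------------------------------------------
# Linear model (OLS backend)
# ---------------------------------------------------------------------------


def linear_model(outcome, design, names: Sequence[str] | None = None) -> RegressionFit:
    """Ordinary least squares with t-based inference; design includes the intercept."""
    import statsmodels.api as sm

    y = np.asarray(outcome, float).ravel()
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_full_rank(X, names)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    fit = RegressionFit(
        names=names,
        coefficients=np.asarray(res.params, float),
        standard_errors=np.asarray(res.bse, float),
        p_values=np.asarray(res.pvalues, float),
        effect_scale=IDENTITY,
        ci_low=np.asarray(ci[:, 0], float),
        ci_high=np.asarray(ci[:, 1], float),
        n_obs=len(y),
    )
    return fit


def binomial_glm(outcome, design, names: Sequence[str] | None = None) -> RegressionFit:
    """Plain (unpenalized) logistic GLM; used by the repeat-size distribution analysis."""
    import statsmodels.api as sm

    y = np.asarray(outcome, float).ravel()
    X = np.asarray(design, float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_full_rank(X, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return _wald(names, np.asarray(res.params), np.asarray(res.bse), ODDS_RATIO, len(y))


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); m defaults to the number of tests."""
    p = np.asarray(p_values, float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def chi2_gof_1df(observed: float, expected: float, n: int) -> tuple[float, float]:
    """1-df goodness of fit of observed vs expected fail counts out of n.

    Returns ``(statistic, p)``.  Degenerate expectations (0 or n) give p = 1.
    """
    if expected <= 0 or expected >= n:
        return 0.0, 1.0
    stat = (observed - expected) ** 2 / expected + (observed - expected) ** 2 / (n - expected)
    return stat, float(sps.chi2.sf(stat, df=1))
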