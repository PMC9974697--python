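"""Logistic selection equation: propensity scores and marginal effects.

Treatment assignment is modeled as a regulator's discrete choice,
``D = 1(theta @ [1, X] > U_R)`` with standard-logistic noise, so the
propensity score is the logistic function of the fitted linear index.  The
logistic form is not a convenience here: the closed-form utility weight used
downstream is derived under it, so no regularized or semiparametric
alternative is offered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "SelectionModel",
    "SeparationError",
    "ConvergenceError",
    "fit_selection",
    "predict_propensity",
    "marginal_effects",
]

# Smallest/largest doubles strictly inside (0, 1): propensities are kept in
# the open interval so that downstream weights stay finite and positive.
_P_LO = np.nextafter(0.0, 1.0)
_P_HI = np.nextafter(1.0, 0.0)


class SeparationError(ValueError):
    """The treated and untreated groups are perfectly separated in covariate
    space, so the logistic MLE does not exist (and utility weights diverge)."""


class ConvergenceError(RuntimeError):
    """The likelihood maximization failed to converge."""


@dataclass
class SelectionModel:
    """Fitted logistic selection equation.

    ``theta`` holds the intercept first, then one coefficient per covariate in
    ``covariate_names``.  ``pseudo_r2`` is McFadden's 1 - LL/LL_null.
    """

    covariate_names: list[str]
    theta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    log_likelihood: float
    ll_null: float
    pseudo_r2: float
    n_obs: int
    converged: bool
    _sm_result: object | None = field(default=None, repr=False, compare=False)

    def linear_index(self, sites: pd.DataFrame) -> np.ndarray:
        X = _design(sites, self.covariate_names)
        return self.theta[0] + X @ self.theta[1:]

    def summary_dict(self) -> dict:
        return {
            "covariates": ["(intercept)"] + list(self.covariate_names),
            "theta": [float(t) for t in self.theta],
            "se": [float(s) for s in self.se],
            "log_likelihood": float(self.log_likelihood),
            "ll_null": float(self.ll_null),
            "pseudo_r2": float(self.pseudo_r2),
            "n_obs": int(self.n_obs),
        }


def _design(sites: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    missing = [c for c in covariates if c not in sites.columns]
    if missing:
        raise ValueError(f"covariates missing from site table: {missing}")
    X = sites[list(covariates)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values")
    return X


def _separating_covariates(X: np.ndarray, D: np.ndarray, names: list[str]) -> list[str]:
    """Single covariates whose treated and untreated supports do not overlap."""
    out = []
    for j, name in enumerate(names):
        t, u = X[D == 1, j], X[D == 0, j]
        if t.min() > u.max() or t.max() < u.min():
            out.append(name)
    return out


def fit_selection(sites: pd.DataFrame, covariates: list[str]) -> SelectionModel:
    """Maximum-likelihood logistic fit of treatment D on covariates + intercept.

    Raises ``SeparationError`` under perfect separation (naming the separating
    covariate(s) when a single covariate is responsible) and
    ``ConvergenceError`` if Newton iterations do not drive the score to zero;
    a partial fit is never returned silently.
    """
    if "D" not in sites.columns:
        raise ValueError("site table has no treatment column 'D'")
    D = sites["D"].to_numpy()
    if not np.isin(D, (0, 1)).all():
        raise ValueError("treatment D must be binary 0/1")
    if (D == 1).sum() < 2 or (D == 0).sum() < 2:
        raise ValueError("need at least 2 sites in each treatment class")
    X = _design(sites, covariates)
    const_cols = [c for c, col in zip(covariates, X.T) if np.ptp(col) == 0]
    if const_cols:
        raise ValueError(f"constant covariates cannot be used: {const_cols}")

    sep = _separating_covariates(X, D, list(covariates))
    if sep:
        raise SeparationError(
            f"perfect separation of treatment by covariate(s) {sep}: "
            "logistic MLE does not exist"
        )

    exog = sm.add_constant(X, has_constant="add")
    model = sm.Logit(D, exog)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saturation diagnosed below
            res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-12)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"perfect separation detected among covariates {list(covariates)}: {exc}"
        ) from exc
    p_hat = np.asarray(res.predict(exog))
    # Quasi-separation drives fitted probabilities to the 0/1 boundary while
    # the likelihood keeps improving: no finite MLE exists.
    if p_hat.min() <= 1e-10 or p_hat.max() >= 1 - 1e-10:
        raise SeparationError(
            f"fitted probabilities reached 0/1: quasi-separation among {list(covariates)}"
        )
    score = model.score(res.params)
    if not res.mle_retvals.get("converged", False) or np.abs(score).max() > 1e-6:
        raise ConvergenceError(
            f"logistic fit did not converge (max |score| = {np.abs(score).max():.3g})"
        )

    ll = float(res.llf)
    ll_null = float(res.llnull)
    return SelectionModel(
        covariate_names=list(covariates),
        theta=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        vcov=np.asarray(res.cov_params(), dtype=float),
        log_likelihood=ll,
        ll_null=ll_null,
        pseudo_r2=float(1.0 - ll / ll_null),
        n_obs=int(res.nobs),
        converged=True,
        _sm_result=res,
    )


def predict_propensity(model: SelectionModel, sites: pd.DataFrame) -> np.ndarray:
    """Propensity scores p(X) = logistic(theta @ [1, X]), strictly inside (0, 1).

    Evaluated through ``scipy.special.expit`` and clipped to the open unit
    interval at machine precision so saturated indices never return exactly 0
    or 1.
    """
    eta = model.linear_index(sites)
    return np.clip(expit(eta), _P_LO, _P_HI)


def _dummy_like(values: np.ndarray) -> bool:
    return bool(np.isin(values, (0.0, 1.0)).all())


def marginal_effects(model: SelectionModel, sites: pd.DataFrame) -> pd.DataFrame:
    """Marginal effects of each covariate on P(D=1), evaluated at covariate means.

    Continuous covariates get the derivative ``p(1-p) * theta_k`` at the mean
    covariate vector; covariates observed only at 0/1 get the discrete change
    ``p(x_mean, k=1) - p(x_mean, k=0)``.  Standard errors are delta-method,
    propagating the full coefficient covariance.
    """
    X = _design(sites, model.covariate_names)
    xbar = np.concatenate([[1.0], X.mean(axis=0)])
    theta = model.theta
    V = model.vcov
    rows = []
    for j, name in enumerate(model.covariate_names):
        k = j + 1  # position in theta (after intercept)
        if _dummy_like(X[:, j]):
            x1 = xbar.copy()
            x0 = xbar.copy()
            x1[k], x0[k] = 1.0, 0.0
            p1, p0 = expit(theta @ x1), expit(theta @ x0)
            effect = p1 - p0
            grad = p1 * (1 - p1) * x1 - p0 * (1 - p0) * x0
            kind = "dummy"
        else:
            p = expit(theta @ xbar)
            effect = p * (1 - p) * theta[k]
            # d/d theta_j of p(1-p) theta_k
            grad = p * (1 - p) * (1 - 2 * p) * theta[k] * xbar
            grad[k] += p * (1 - p)
            kind = "continuous"
        se = float(np.sqrt(grad @ V @ grad))
        rows.append({"covariate": name, "kind": kind, "marginal_effect": float(effect), "se": se})
    return pd.DataFrame(rows)
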