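"""Constrained maximum-likelihood fitting and asymptotic inference.

Estimation follows a two-step scheme: starting values from a Poisson GEE
with AR(1) working correlation (shrunk toward independence if they violate
the validity constraints), followed by maximization of the joint
log-likelihood with a logarithmic-barrier outer loop (barrier on every
validity slack and on 1 - alpha^2) around BFGS inner iterations that use
the analytic gradient.  The estimator covariance is the inverse observed
information, with the Hessian obtained by central finite differences of
the analytic gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from . import gee
from .exceptions import FitError, SingularInformationError, ValidationError
from .model import (LongitudinalDataset, ModelParams, check_constraints,
                    grad_log_likelihood, log_likelihood,
                    penalized_objective)

__all__ = ["FitResult", "OptimizerSettings", "initial_values", "fit_ml",
           "observed_information", "information_criteria",
           "likelihood_ratio_test", "wald_table"]


@dataclass
class OptimizerSettings:
    """Tuning knobs for the barrier optimization."""

    mu_ratio: float = 0.1       # geometric decay of the barrier weight
    outer_iter: int = 8
    inner_iter: int = 200
    tol_loglik: float = 1e-8    # outer convergence: |delta loglik|
    tol_grad: float = 1e-5      # max-norm of the likelihood gradient


@dataclass
class FitResult:
    """Maximum-likelihood estimates with asymptotic inference."""

    params_hat: ModelParams
    cov: np.ndarray
    loglik: float
    aic: float
    bic: float
    wald_table: pd.DataFrame
    converged: bool
    n_obs: int
    iterations: int
    grad_norm: float = float("nan")
    alpha_estimable: bool = True
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        """Standard errors for (beta..., alpha)."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))


def shrink_to_feasible(data: LongitudinalDataset, beta,
                       alpha: float) -> ModelParams:
    """Halve alpha toward 0 until the validity constraints hold at beta."""
    beta = np.asarray(beta, dtype=float)
    for _ in range(60):
        if alpha == 0.0 or check_constraints(
                data, ModelParams(beta, alpha)).feasible:
            break
        alpha *= 0.5
        if abs(alpha) < 1e-8:
            alpha = 0.0
    params = ModelParams(beta, alpha)
    if not check_constraints(data, params).feasible:  # pragma: no cover
        raise FitError("no feasible starting values found")
    return params


def initial_values(data: LongitudinalDataset) -> ModelParams:
    """Starting values: GEE-Poisson-AR(1) estimates, with alpha halved
    toward 0 until the validity constraints hold; plain Poisson regression
    (alpha = 0) is the fallback."""
    try:
        if data.n_pairs == 0:
            raise FitError("no adjacent pairs")
        g = gee.fit_gee_ar1(data)
        beta, alpha = g.beta_hat, float(g.alpha_hat)
    except FitError:
        g = gee.fit_poisson(data)
        beta, alpha = g.beta_hat, 0.0
    return shrink_to_feasible(data, beta, alpha)


def fit_ml(data: LongitudinalDataset, start: ModelParams | None = None,
           settings: OptimizerSettings | None = None) -> FitResult:
    """Maximize the joint log-likelihood subject to the validity
    constraints via a log-barrier outer loop with BFGS inner iterations.

    Degenerate datasets in which no subject has two or more visits are
    fitted as plain Poisson (alpha fixed at 0, SE undefined).
    """
    settings = settings or OptimizerSettings()
    if data.n_pairs == 0:
        return _fit_poisson_only(data)
    if start is None:
        start = initial_values(data)
    if not check_constraints(data, start).feasible:
        raise FitError("starting values violate the validity constraints")

    theta = start.theta
    ll_prev = log_likelihood(data, start)
    mu = 1e-4 * max(1.0, abs(ll_prev))
    n_inner = 0
    converged = False

    def objective(t, mu):
        return penalized_objective(data, t, mu)

    grad_norm = np.inf
    for outer in range(settings.outer_iter):
        res = optimize.minimize(
            objective, theta, args=(mu,), jac=True, method="BFGS",
            options={"maxiter": settings.inner_iter, "gtol": 1e-8})
        n_inner += res.nit
        theta = res.x
        ll_now = log_likelihood(data, ModelParams.from_theta(theta))
        grad_norm = float(np.max(np.abs(
            grad_log_likelihood(data, ModelParams.from_theta(theta)))))
        if abs(ll_now - ll_prev) < settings.tol_loglik:
            # outer loop settled; Newton polish below enforces the
            # gradient tolerance at the raw-likelihood optimum
            converged = grad_norm < settings.tol_grad
            ll_prev = ll_now
            break
        ll_prev = ll_now
        mu *= settings.mu_ratio

    # polish: interior optima are unconstrained stationary points, so a
    # few Newton steps on the raw likelihood remove the O(mu) barrier bias
    # (BFGS alone stalls on precision loss for badly scaled covariates)
    for _ in range(6):
        if grad_norm < 1e-2 * settings.tol_grad:
            break
        cand = ModelParams.from_theta(theta)
        grad = grad_log_likelihood(data, cand)
        info = observed_information(data, cand)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        trial = ModelParams.from_theta(theta + step)
        try:
            feasible = check_constraints(data, trial).feasible
            ll_trial = log_likelihood(data, trial) if feasible else -np.inf
        except Exception:
            break
        if not feasible or ll_trial < ll_prev - 1e-9:
            break
        theta = trial.theta
        ll_prev = ll_trial
        n_inner += 1
        grad_norm = float(np.max(np.abs(
            grad_log_likelihood(data, trial))))
    converged = converged or grad_norm < settings.tol_grad

    params_hat = ModelParams.from_theta(theta)
    return _finalize(data, params_hat, ll_prev, converged, n_inner,
                     grad_norm)


def _fit_poisson_only(data: LongitudinalDataset) -> FitResult:
    g = gee.fit_poisson(data)
    params = ModelParams(g.beta_hat, 0.0)
    ll = log_likelihood(data, params)
    p = data.p
    cov = np.full((p + 1, p + 1), np.nan)
    cov[:p, :p] = g.naive_cov
    aic, bic = information_criteria(ll, p, data.n_obs)
    table = wald_table(params, cov, data.covariate_names)
    return FitResult(params_hat=params, cov=cov, loglik=ll, aic=aic,
                     bic=bic, wald_table=table, converged=g.converged,
                     n_obs=data.n_obs, iterations=g.iterations,
                     alpha_estimable=False,
                     message="no repeated measurements: alpha fixed at 0, "
                             "SE undefined")


def _finalize(data, params_hat, ll, converged, iterations, grad_norm):
    p = data.p
    info = observed_information(data, params_hat)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as e:
        raise SingularInformationError(
            f"observed information is singular at the optimum "
            f"(condition number {np.linalg.cond(info):.3g})") from e
    cov = 0.5 * (cov + cov.T)
    aic, bic = information_criteria(ll, p + 1, data.n_obs)
    table = wald_table(params_hat, cov, data.covariate_names)
    return FitResult(params_hat=params_hat, cov=cov, loglik=ll, aic=aic,
                     bic=bic, wald_table=table, converged=converged,
                     n_obs=data.n_obs, iterations=iterations,
                     grad_norm=grad_norm)


def observed_information(data: LongitudinalDataset, params: ModelParams,
                         rel_step: float = 1e-6) -> np.ndarray:
    """Negative Hessian of the log-likelihood at ``params``, by central
    finite differences of the analytic gradient, symmetrized."""
    theta = params.theta
    k = theta.size
    H = np.zeros((k, k))
    for j in range(k):
        h = rel_step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = grad_log_likelihood(data, ModelParams.from_theta(tp))
        gm = grad_log_likelihood(data, ModelParams.from_theta(tm))
        H[:, j] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    return -H


def information_criteria(loglik: float, k: int, n_obs: int):
    """AIC and BIC; ``n_obs`` is the total number of observations."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n_obs < 1:
        raise ValidationError("n_obs must be >= 1")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n_obs)
    return float(aic), float(bic)


def likelihood_ratio_test(fit_full: FitResult, fit_reduced: FitResult):
    """LRT of a nested reduced model: (statistic, df, p-value)."""
    delta = fit_full.loglik - fit_reduced.loglik
    if delta < -1e-6:
        warnings.warn(
            "full-model log-likelihood below reduced model's: models may "
            "not be nested or a fit did not converge", RuntimeWarning)
    stat = max(0.0, 2.0 * delta)

    def n_free(fit):
        return fit.params_hat.beta.size + (1 if fit.alpha_estimable else 0)

    df = max(n_free(fit_full) - n_free(fit_reduced), 1)
    return stat, df, float(chi2.sf(stat, df))


def wald_table(params: ModelParams, cov: np.ndarray,
               covariate_names) -> pd.DataFrame:
    """Per-parameter estimate, SE, Wald statistic (est/SE)^2 and
    chi-square(1) upper-tail p-value; the correlation row reports only
    estimate and SE."""
    est = params.theta
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(cov))
    wald = (est / se) ** 2
    pval = chi2.sf(wald, df=1)
    names = list(covariate_names) + ["alpha"]
    table = pd.DataFrame({"estimate": est, "se": se, "wald": wald,
                          "p_value": pval}, index=names)
    table.loc["alpha", ["wald", "p_value"]] = np.nan
    return table
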