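"""Minimal GEE for Poisson marginal means with an AR(1) working correlation.

Used both for starting values of the likelihood fit and as the
semi-parametric comparator that ignores overdispersion.  Only the naive
(model-based) covariance is produced; sandwich covariance is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import FitError
from .model import LongitudinalDataset

__all__ = ["GEEResult", "fit_poisson", "fit_gee_ar1", "dispersion_estimate"]


@dataclass
class GEEResult:
    """Estimates from a Poisson GEE fit.

    ``naive_cov`` is the model-based covariance of beta_hat; ``alpha_se``
    is a working-model standard error for the correlation parameter (NaN
    for the independence fit).
    """

    beta_hat: np.ndarray
    alpha_hat: float
    naive_cov: np.ndarray
    phi_hat: float
    converged: bool
    alpha_se: float = float("nan")
    iterations: int = 0

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_cov))


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")


def fit_poisson(data: LongitudinalDataset, max_iter: int = 100,
                tol: float = 1e-10) -> GEEResult:
    """Poisson MLE by iteratively reweighted least squares
    (independence working model, alpha fixed at 0)."""
    X, y = data.X, data.y.astype(float)
    _check_design(X)
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))  # intercept-only start
    llast = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = np.exp(X @ beta)
        W = lam
        M = X.T @ (W[:, None] * X)
        score = X.T @ (y - lam)
        try:
            step = np.linalg.solve(M, score)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise FitError("singular Fisher information in IRLS") from e
        beta = beta + step
        ll = float(np.sum(y * (X @ beta) - np.exp(X @ beta)))
        if abs(ll - llast) < tol:
            converged = True
            break
        llast = ll
    lam = np.exp(X @ beta)
    M = X.T @ (lam[:, None] * X)
    cov = np.linalg.inv(M)
    phi = dispersion_estimate(data, beta)
    return GEEResult(beta_hat=beta, alpha_hat=0.0, naive_cov=cov,
                     phi_hat=phi, converged=converged, iterations=it)


def dispersion_estimate(data: LongitudinalDataset, beta_hat) -> float:
    """Average over subjects of the per-subject mean squared Pearson
    residual: phi_hat = (1/m) sum_i Z_i'Z_i / n_i."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    lam = np.exp(data.X @ beta_hat)
    if np.any(lam <= 0):
        raise FloatingPointError("fitted mean underflowed to zero")
    z2 = (data.y - lam) ** 2 / lam
    total = 0.0
    for s, o in zip(data.subjects, data.first_idx):
        total += z2[o:o + s.n].sum() / s.n
    return float(total / data.m)


def _ar1_inverse(n: int, alpha: float) -> np.ndarray:
    """Closed-form inverse of the n x n AR(1) correlation matrix."""
    if n == 1:
        return np.ones((1, 1))
    Rinv = np.zeros((n, n))
    d = 1.0 / (1.0 - alpha * alpha)
    np.fill_diagonal(Rinv, (1.0 + alpha * alpha) * d)
    Rinv[0, 0] = Rinv[n - 1, n - 1] = d
    idx = np.arange(n - 1)
    Rinv[idx, idx + 1] = Rinv[idx + 1, idx] = -alpha * d
    return Rinv


def _all_lag_pairs(data: LongitudinalDataset):
    """Index arrays (j, k, lag) over every within-subject pair j < k."""
    a, b, lags = [], [], []
    for s, o in zip(data.subjects, data.first_idx):
        for j in range(s.n):
            for k in range(j + 1, s.n):
                a.append(o + j)
                b.append(o + k)
                lags.append(k - j)
    return (np.array(a, dtype=np.intp), np.array(b, dtype=np.intp),
            np.array(lags, dtype=float))


def _solve_alpha_ar1(s: np.ndarray, lags: np.ndarray,
                     alpha0: float) -> float:
    """Root of the AR(1) association estimating equation
    ``sum_p lag * a^(lag-1) * (s_p - a^lag) = 0`` over scaled
    cross-products s_p, by Newton iteration with bisection fallback."""

    def U(a):
        return float(np.sum(lags * a ** (lags - 1) * (s - a ** lags)))

    higher = lags > 1  # lag-1 terms have zero curvature coefficient
    a = float(np.clip(alpha0, -0.95, 0.95))
    for _ in range(50):
        u = U(a)
        du = float(np.sum(lags[higher] * (lags[higher] - 1)
                          * a ** (lags[higher] - 2) * s[higher])
                   - np.sum(lags * (2 * lags - 1) * a ** (2 * lags - 2)))
        if du == 0:
            break
        step = u / du
        a_new = float(np.clip(a - step, -0.99, 0.99))
        if abs(a_new - a) < 1e-12:
            a = a_new
            break
        a = a_new
    if abs(U(a)) > 1e-6 * max(1.0, float(np.abs(s).sum())):
        # Newton failed; bisection if a sign change exists
        from scipy.optimize import brentq
        try:
            a = float(brentq(U, -0.99, 0.99))
        except ValueError:
            a = float(np.clip(np.mean(s[lags == 1]), -0.99, 0.99))
    return a


def fit_gee_ar1(data: LongitudinalDataset, max_iter: int = 200,
                tol: float = 1e-8,
                fix_alpha: float | None = None) -> GEEResult:
    """GEE for the Poisson mean model with AR(1) working correlation.

    Alternates generalized least-squares updates of beta with estimation
    of alpha from the association estimating equation over every
    within-subject pair of Pearson residuals at all lags (working
    correlation ``alpha^lag``), with cross-products scaled by the Pearson
    dispersion ``phi = sum z^2 / N``.

    Model-based (naive) precision assumes the working structure is
    correct: the covariance of beta_hat is
    ``phi * (sum_i D_i' V_i^{-1} D_i)^{-1}`` and
    ``var(alpha_hat) = 1 / sum_p lag^2 alpha^(2 lag - 2)``, which
    understates the sampling variability of alpha_hat under serial
    overdispersion.  These conventions are calibrated against geeglm's
    AR(1) moment estimator and naive variances.
    """
    if data.n_pairs == 0:
        raise FitError("alpha inestimable: no subject has 2+ visits")
    X, y = data.X, data.y.astype(float)
    _check_design(X)
    p = X.shape[1]
    n_obs = data.n_obs
    pj, pk, lags = _all_lag_pairs(data)

    beta = fit_poisson(data).beta_hat
    alpha = 0.0
    converged = False
    it = 0
    M = np.eye(p)
    phi = 1.0
    for it in range(1, max_iter + 1):
        lam = np.exp(X @ beta)
        z = (y - lam) / np.sqrt(lam)
        phi = float(z @ z / n_obs)
        if fix_alpha is None:
            s = z[pj] * z[pk] / phi
            alpha_new = _solve_alpha_ar1(s, lags, alpha)
        else:
            alpha_new = float(fix_alpha)

        # one GLS scoring step for beta at alpha_new
        M = np.zeros((p, p))
        score = np.zeros(p)
        for s, o in zip(data.subjects, data.first_idx):
            n = s.n
            sl = slice(o, o + n)
            Rinv = _ar1_inverse(n, alpha_new)
            sql = np.sqrt(lam[sl])
            # D_i'V_i^{-1} = X_i' S_i R^{-1} S_i^{-1}, S_i = diag(sqrt lam)
            B = (sql[:, None] * Rinv) * (1.0 / sql)[None, :]
            XtB = s.X.T @ B
            M += XtB @ (s.X * lam[sl, None])
            score += XtB @ (y[sl] - lam[sl])
        try:
            step = np.linalg.solve(M, score)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise FitError("singular GEE working information") from e
        beta_new = beta + step
        delta = max(np.max(np.abs(step)) / (1.0 + np.max(np.abs(beta))),
                    abs(alpha_new - alpha))
        beta, alpha = beta_new, float(alpha_new)
        if delta < tol:
            converged = True
            break

    naive_cov = phi * np.linalg.inv(M)
    alpha_se = (float(np.sum(lags ** 2 * alpha ** (2 * lags - 2)) ** -0.5)
                if fix_alpha is None else float("nan"))
    return GEEResult(beta_hat=beta, alpha_hat=alpha, naive_cov=naive_cov,
                     phi_hat=phi, converged=converged, alpha_se=alpha_se,
                     iterations=it)
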