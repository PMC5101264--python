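"""Moment structure, validity constraints, log-likelihood and gradient for
first-order antedependent Poisson series.

The model for a subject's ordered counts ``Y_1, ..., Y_n``:

* ``Y_1 ~ Poisson(lambda_1)`` with ``lambda_j = exp(x_j' beta)``,
* for ``j >= 2``, ``Y_j | Y_{j-1} ~ Poisson(lambda*_j)`` where

  ``lambda*_j = lambda_j + alpha * (sigma_j / sigma_{j-1}) * (y_{j-1} - lambda_{j-1})``

with marginal variances ``sigma_1^2 = lambda_1`` and
``sigma_j^2 = lambda_j / (1 - alpha^2)`` for ``j >= 2``.  The construction
induces an AR(1) correlation (``corr(Y_j, Y_{j+t}) = alpha^t``) and
overdispersion ``var/mean = 1/(1 - alpha^2)`` at non-initial visits.

The standard-deviation ratio therefore has two regimes:

* ``j == 2``:  ``sigma_2/sigma_1 = sqrt(lambda_2 / ((1 - alpha^2) lambda_1))``
* ``j >= 3``:  ``sigma_j/sigma_{j-1} = sqrt(lambda_j / lambda_{j-1})``

and the ``alpha``-derivative differs between the two, which is why the case
split is carried explicitly throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .exceptions import ConstraintError, InfeasiblePointError, ValidationError

__all__ = [
    "Subject",
    "LongitudinalDataset",
    "ModelParams",
    "MarginalMoments",
    "ConditionalMoments",
    "ConstraintReport",
    "marginal_mean",
    "marginal_sd",
    "conditional_mean",
    "check_constraints",
    "log_likelihood",
    "grad_log_likelihood",
    "alpha_bound",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subject:
    """One subject's ordered, equally spaced count series.

    Attributes
    ----------
    y : ndarray of int, shape (n_i,)
        Non-negative counts, one per visit, in visit order.
    X : ndarray of float, shape (n_i, p)
        Covariate rows; first column is the intercept (all ones by
        convention, not enforced).
    subject_id : object
        Opaque label.
    """

    y: np.ndarray
    X: np.ndarray
    subject_id: object = None

    def __post_init__(self):
        y = np.asarray(self.y)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if y.ndim != 1 or y.size < 1:
            raise ValidationError(f"subject {self.subject_id}: y must be a "
                                  "non-empty 1-d sequence")
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValidationError(f"subject {self.subject_id}: counts must be "
                                  "non-negative integers")
        if X.shape[0] != y.size:
            raise ValidationError(f"subject {self.subject_id}: X has "
                                  f"{X.shape[0]} rows for {y.size} visits")
        object.__setattr__(self, "y", y.astype(np.int64))
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.y.size


class LongitudinalDataset:
    """Collection of independent subjects with a common covariate dimension.

    Visits are taken to be consecutively indexed and equally spaced; only
    the ordering is represented, not timestamps.
    """

    def __init__(self, subjects: Sequence[Subject],
                 covariate_names: Sequence[str] | None = None):
        subjects = list(subjects)
        if not subjects:
            raise ValidationError("dataset must contain at least one subject")
        p = subjects[0].X.shape[1]
        for s in subjects:
            if s.X.shape[1] != p:
                raise ValidationError(
                    f"subject {s.subject_id}: covariate dimension "
                    f"{s.X.shape[1]} != {p}")
        if covariate_names is not None and len(covariate_names) != p:
            raise ValidationError("covariate_names length mismatch")
        self.subjects = subjects
        self.covariate_names = (list(covariate_names) if covariate_names
                                else [f"x{k}" for k in range(p)])
        self._stack()

    def _stack(self) -> None:
        # flat arrays + index bookkeeping for vectorised likelihood work
        ns = np.array([s.n for s in self.subjects])
        offsets = np.concatenate([[0], np.cumsum(ns)])
        self.y = np.concatenate([s.y for s in self.subjects])
        self.X = np.vstack([s.X for s in self.subjects])
        self.first_idx = offsets[:-1]
        # adjacent (previous, current) pairs and the j==2 flag
        prev, cur, second = [], [], []
        for i, n in enumerate(ns):
            o = offsets[i]
            for j in range(1, n):
                prev.append(o + j - 1)
                cur.append(o + j)
                second.append(j == 1)
        self.prev_idx = np.array(prev, dtype=np.intp)
        self.cur_idx = np.array(cur, dtype=np.intp)
        self.is_second = np.array(second, dtype=bool)

    @property
    def m(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_pairs(self) -> int:
        return self.cur_idx.size

    def __len__(self) -> int:
        return len(self.subjects)

    def __repr__(self) -> str:
        return (f"LongitudinalDataset(m={self.m}, n_obs={self.n_obs}, "
                f"p={self.p})")


@dataclass(frozen=True)
class ModelParams:
    """Regression coefficients (log-mean scale) and adjacent correlation."""

    beta: np.ndarray
    alpha: float = 0.0

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if beta.ndim != 1:
            raise ValidationError("beta must be a vector")
        if not -1.0 < self.alpha < 1.0:
            raise ConstraintError(f"alpha={self.alpha} outside (-1, 1)")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha", float(self.alpha))

    @property
    def theta(self) -> np.ndarray:
        """Packed parameter vector (beta..., alpha)."""
        return np.concatenate([self.beta, [self.alpha]])

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "ModelParams":
        theta = np.asarray(theta, dtype=float)
        return cls(beta=theta[:-1], alpha=float(theta[-1]))


@dataclass(frozen=True)
class MarginalMoments:
    """Marginal mean and standard deviation of one observation."""
    lam: float
    sd: float


@dataclass(frozen=True)
class ConditionalMoments:
    """Conditional mean (and its log) of an observation given its
    predecessor."""
    lam_star: float
    theta_star: float


@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of the validity-constraint check at a given (beta, alpha)."""
    feasible: bool
    alpha_bound: float
    slacks: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Elementary moments
# ---------------------------------------------------------------------------

def marginal_mean(x, beta) -> float:
    """exp(x' beta), the marginal expected count for one covariate row."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape != beta.shape:
        raise ValidationError(f"covariate row length {x.shape} != beta "
                              f"length {beta.shape}")
    return float(np.exp(x @ beta))


def marginal_sd(lam: float, alpha: float, is_first_visit: bool) -> float:
    """Marginal standard deviation: sqrt(lam) at the first visit,
    sqrt(lam / (1 - alpha^2)) afterwards."""
    if lam <= 0:
        raise ValidationError("lam must be positive")
    if not -1.0 < alpha < 1.0:
        raise ConstraintError(f"alpha={alpha} outside (-1, 1)")
    if is_first_visit:
        return float(np.sqrt(lam))
    return float(np.sqrt(lam / (1.0 - alpha * alpha)))


def conditional_mean(lam_cur: float, lam_prev: float, sd_cur: float,
                     sd_prev: float, y_prev: float, alpha: float) -> float:
    """Conditional expected count given the previous count.

    Returns ``lam_cur + alpha * (sd_cur / sd_prev) * (y_prev - lam_prev)``,
    which may be non-positive; callers must check before taking logs.
    """
    return float(lam_cur + alpha * (sd_cur / sd_prev) * (y_prev - lam_prev))


# ---------------------------------------------------------------------------
# Vectorised internals
# ---------------------------------------------------------------------------

def _pair_terms(data: LongitudinalDataset, beta: np.ndarray, alpha: float):
    """Per-observation means plus, for each adjacent pair, the correlation
    weight ``r = alpha * sigma_cur/sigma_prev`` and its alpha-derivative.

    Returns (lam, lam_prev, lam_cur, r, dr_dalpha, ratio_sqrt) where
    ratio_sqrt = sqrt(lam_cur/lam_prev) and arrays are aligned with
    data.cur_idx.
    """
    eta = data.X @ beta
    lam = np.exp(eta)
    lam_prev = lam[data.prev_idx]
    lam_cur = lam[data.cur_idx]
    ratio_sqrt = np.sqrt(lam_cur / lam_prev)
    one_m_a2 = 1.0 - alpha * alpha
    # sd ratio: extra 1/sqrt(1-alpha^2) factor only for the j==2 pair
    c = np.where(data.is_second, 1.0 / np.sqrt(one_m_a2), 1.0)
    r = alpha * c * ratio_sqrt
    # d r / d alpha: (1-a^2)^(-3/2) for j==2, 1 for j>=3, times ratio_sqrt
    ca = np.where(data.is_second, one_m_a2 ** -1.5, 1.0)
    dr_dalpha = ca * ratio_sqrt
    return lam, lam_prev, lam_cur, r, dr_dalpha, ratio_sqrt


def _slacks(data: LongitudinalDataset, beta: np.ndarray,
            alpha: float) -> np.ndarray:
    """Per-pair validity slack ``lam_cur - alpha*(sd_cur/sd_prev)*lam_prev``
    (equal to the conditional mean at y_prev = 0)."""
    _, lam_prev, lam_cur, r, _, _ = _pair_terms(data, beta, alpha)
    return lam_cur - r * lam_prev


def alpha_bound(data: LongitudinalDataset, beta,
                tol: float = 1e-10) -> float:
    """Supremum of alpha in (0, 1] keeping every validity slack positive at
    fixed beta, found by bisection (the minimal slack is continuous and
    decreasing in alpha on [0, 1))."""
    beta = np.asarray(beta, dtype=float)
    if data.n_pairs == 0:
        return 1.0
    hi = 1.0 - 1e-12
    if np.min(_slacks(data, beta, hi)) > 0:
        return 1.0
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.min(_slacks(data, beta, mid)) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def check_constraints(data: LongitudinalDataset,
                      params: ModelParams) -> ConstraintReport:
    """Evaluate the likelihood-validity constraints at (beta, alpha).

    Feasibility requires |alpha| < 1 (enforced by ModelParams) and every
    adjacent-pair slack strictly positive.  The reported alpha_bound is the
    supremum of feasible alpha >= 0 at this beta.
    """
    if params.beta.size != data.p:
        raise ValidationError(f"beta length {params.beta.size} != p={data.p}")
    slacks = _slacks(data, params.beta, params.alpha)
    feasible = bool(np.all(slacks > 0))
    return ConstraintReport(feasible=feasible,
                            alpha_bound=alpha_bound(data, params.beta),
                            slacks=slacks)


def log_likelihood(data: LongitudinalDataset, params: ModelParams) -> float:
    """Joint log-likelihood of the antedependent Poisson model.

    Sum over subjects of the first-visit Poisson log-pmf plus the
    conditional Poisson log-pmfs of later visits.  Raises
    InfeasiblePointError if any conditional mean is non-positive.
    """
    beta, alpha = params.beta, params.alpha
    if beta.size != data.p:
        raise ValidationError(f"beta length {beta.size} != p={data.p}")
    lam, lam_prev, lam_cur, r, _, _ = _pair_terms(data, beta, alpha)
    y = data.y
    f = data.first_idx
    lam1 = lam[f]
    ll = np.sum(y[f] * np.log(lam1) - lam1 - gammaln(y[f] + 1.0))
    if data.n_pairs:
        lam_star = lam_cur + r * (y[data.prev_idx] - lam_prev)
        if np.any(lam_star <= 0):
            raise InfeasiblePointError(
                "non-positive conditional mean at the evaluation point")
        yc = y[data.cur_idx]
        ll += np.sum(yc * np.log(lam_star) - lam_star - gammaln(yc + 1.0))
    return float(ll)


def grad_log_likelihood(data: LongitudinalDataset,
                        params: ModelParams) -> np.ndarray:
    """Analytic gradient of log_likelihood, length p + 1: (d/dbeta, d/dalpha).

    Derived by the chain rule through the conditional means; the sd-ratio
    depends on alpha only at j == 2 pairs (through 1/sqrt(1 - alpha^2)),
    while its beta-derivative has the common form (r/2)(x_cur - x_prev).
    """
    beta, alpha = params.beta, params.alpha
    if beta.size != data.p:
        raise ValidationError(f"beta length {beta.size} != p={data.p}")
    lam, lam_prev, lam_cur, r, dr_da, _ = _pair_terms(data, beta, alpha)
    y = data.y
    f = data.first_idx
    g_beta = (y[f] - lam[f]) @ data.X[f]
    g_alpha = 0.0
    if data.n_pairs:
        yp = y[data.prev_idx]
        resid_prev = yp - lam_prev
        lam_star = lam_cur + r * resid_prev
        if np.any(lam_star <= 0):
            raise InfeasiblePointError(
                "non-positive conditional mean at the evaluation point")
        w = y[data.cur_idx] / lam_star - 1.0  # d ll / d lam_star
        Xc = data.X[data.cur_idx]
        Xp = data.X[data.prev_idx]
        # d lam*/d beta = lam_cur x_cur + (r/2)(x_cur - x_prev)(y_prev -
        # lam_prev) - r lam_prev x_prev
        coef_cur = w * (lam_cur + 0.5 * r * resid_prev)
        coef_prev = w * (-0.5 * r * resid_prev - r * lam_prev)
        g_beta = g_beta + coef_cur @ Xc + coef_prev @ Xp
        g_alpha = float(np.sum(w * dr_da * resid_prev))
    return np.concatenate([np.asarray(g_beta, dtype=float).ravel(),
                           [g_alpha]])


def penalized_objective(data: LongitudinalDataset, theta: np.ndarray,
                        mu: float):
    """Fused evaluation of -(loglik + mu * barrier) and its gradient in a
    single pass over the data (the optimizer's hot path).

    Returns (value, gradient); value is +inf (with a zero gradient) at
    infeasible points.
    """
    theta = np.asarray(theta, dtype=float)
    beta, alpha = theta[:-1], float(theta[-1])
    one_m_a2 = 1.0 - alpha * alpha
    if one_m_a2 <= 0:
        return np.inf, np.zeros_like(theta)
    lam, lam_prev, lam_cur, r, dr_da, _ = _pair_terms(data, beta, alpha)
    y = data.y
    f = data.first_idx
    lam1 = lam[f]
    ll = np.sum(y[f] * np.log(lam1) - lam1 - gammaln(y[f] + 1.0))
    g_beta = (y[f] - lam1) @ data.X[f]
    g_alpha = 0.0
    B = 0.0
    gB = np.zeros_like(theta)
    if data.n_pairs:
        yp = y[data.prev_idx]
        resid_prev = yp - lam_prev
        lam_star = lam_cur + r * resid_prev
        slack = lam_cur - r * lam_prev
        if np.any(slack <= 0) or np.any(lam_star <= 0):
            return np.inf, np.zeros_like(theta)
        yc = y[data.cur_idx]
        ll += np.sum(yc * np.log(lam_star) - lam_star - gammaln(yc + 1.0))
        w = yc / lam_star - 1.0
        Xc = data.X[data.cur_idx]
        Xp = data.X[data.prev_idx]
        coef_cur = w * (lam_cur + 0.5 * r * resid_prev)
        coef_prev = w * (-0.5 * r * resid_prev - r * lam_prev)
        g_beta = g_beta + coef_cur @ Xc + coef_prev @ Xp
        g_alpha = float(np.sum(w * dr_da * resid_prev))
        if mu:
            B = float(np.sum(np.log(slack)) + np.log(one_m_a2))
            inv = 1.0 / slack
            bc = inv * (lam_cur - 0.5 * r * lam_prev)
            bp = inv * (-0.5 * r * lam_prev)
            gB[:-1] = bc @ Xc + bp @ Xp
            gB[-1] = (-np.sum(inv * dr_da * lam_prev)
                      - 2.0 * alpha / one_m_a2)
    grad = np.concatenate([np.asarray(g_beta).ravel(), [g_alpha]])
    return -(ll + mu * B), -(grad + mu * gB)


def barrier_terms(data: LongitudinalDataset, params: ModelParams):
    """Log-barrier value and gradient over the validity constraints.

    Returns (B, gradB) with B = sum(log slack) + log(1 - alpha^2), or
    (-inf, None) when infeasible.  Used by the barrier optimiser.
    """
    beta, alpha = params.beta, params.alpha
    _, lam_prev, lam_cur, r, dr_da, _ = _pair_terms(data, beta, alpha)
    slack = lam_cur - r * lam_prev
    one_m_a2 = 1.0 - alpha * alpha
    if np.any(slack <= 0) or one_m_a2 <= 0:
        return -np.inf, None
    B = float(np.sum(np.log(slack)) + np.log(one_m_a2))
    inv = 1.0 / slack
    Xc = data.X[data.cur_idx]
    Xp = data.X[data.prev_idx]
    # d slack/d beta = lam_cur x_cur - r lam_prev (x_cur + x_prev)/2
    coef_cur = inv * (lam_cur - 0.5 * r * lam_prev)
    coef_prev = inv * (-0.5 * r * lam_prev)
    gB_beta = coef_cur @ Xc + coef_prev @ Xp
    gB_alpha = float(-np.sum(inv * dr_da * lam_prev)) - 2.0 * alpha / one_m_a2
    return B, np.concatenate([np.asarray(gB_beta).ravel(), [gB_alpha]])
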