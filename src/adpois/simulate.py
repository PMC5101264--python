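"""Exact simulation of the antedependent Poisson process and of the
epilepsy-trial-calibrated covariate design used in the simulation study.

Covariate design (two equal arms, 4 equally spaced visits by default):
treatment indicator fixed by subject index, a Poisson-distributed baseline
count held constant across a subject's visits, and an age drawn from a
normal distribution truncated below by rejection and rounded to a whole
number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConstraintError, ValidationError
from .model import LongitudinalDataset, Subject, _slacks

__all__ = ["SimulationConfig", "DEFAULT_BETA", "simulate_covariates",
           "simulate_counts", "simulate_dataset"]

#: Regression coefficients used throughout the simulation study:
#: (intercept, treatment, baseline count, age).
DEFAULT_BETA = np.array([0.4467, -0.1659, 0.0232, 0.0258])


@dataclass
class SimulationConfig:
    """Population design for the replicated simulation study."""

    m: int = 60
    alpha: float = 0.2
    n_per_subject: int = 4
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    baseline_mean: float = 31.22
    age_mean: float = 28.3
    age_sd: float = 6.261
    age_min: float = 18.0
    replicates: int = 1000
    seed: int | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.m < 2 or self.m % 2:
            raise ValidationError("m must be an even integer >= 2")
        if not 0.0 <= self.alpha < 1.0:
            raise ConstraintError(
                f"simulator requires alpha in [0, 1); got {self.alpha}")
        if self.n_per_subject < 1:
            raise ValidationError("n_per_subject must be >= 1")

    @property
    def covariate_names(self) -> list[str]:
        return ["intercept", "treatment", "baseline", "age"]


def simulate_covariates(cfg: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """One covariate row per subject: (1, treatment, baseline, age).

    Treatment is 1 for the first m/2 subjects and 0 for the rest, so group
    sizes are exactly equal.  Baseline ~ Poisson(baseline_mean); age is
    normal with draws below age_min discarded and redrawn, then rounded.
    Covariates are constant within subject.
    """
    m = cfg.m
    treat = np.zeros(m)
    treat[: m // 2] = 1.0
    baseline = rng.poisson(cfg.baseline_mean, size=m).astype(float)
    age = np.empty(m)
    filled = 0
    while filled < m:
        draw = rng.normal(cfg.age_mean, cfg.age_sd, size=m - filled)
        keep = draw[draw >= cfg.age_min]
        age[filled:filled + keep.size] = keep
        filled += keep.size
    age = np.rint(age)
    return np.column_stack([np.ones(m), treat, baseline, age])


def simulate_counts(X_subjects: np.ndarray, beta, alpha: float,
                    rng: np.random.Generator,
                    n_per_subject: int = 4,
                    covariate_names=None) -> LongitudinalDataset:
    """Draw antedependent Poisson series for subjects with per-subject
    covariate rows held constant across visits.

    Sampling is sequential from the model's own conditionals:
    Y_1 ~ Poisson(lam_1), then Y_j | Y_{j-1} ~ Poisson(lam*_j).  Refuses
    to simulate if the validity constraints fail at (beta, alpha) or if
    alpha < 0 (for which positivity of lam* cannot hold uniformly over
    previous counts).
    """
    beta = np.asarray(beta, dtype=float)
    X_subjects = np.atleast_2d(np.asarray(X_subjects, dtype=float))
    if not 0.0 <= alpha < 1.0:
        raise ConstraintError(f"simulator requires alpha in [0, 1); "
                              f"got {alpha}")
    m = X_subjects.shape[0]
    n = n_per_subject
    lam = np.exp(X_subjects @ beta)  # constant across a subject's visits
    if n >= 2:
        # adjacent-pair slack; with equal within-subject means the j=2 pair
        # (factor 1/sqrt(1-alpha^2)) is binding
        ratio2 = alpha / np.sqrt(1.0 - alpha * alpha)
        if np.any(lam - ratio2 * lam <= 0):
            raise ConstraintError(
                "validity constraint violated at the requested (beta, alpha)")
    Y = np.empty((m, n), dtype=np.int64)
    Y[:, 0] = rng.poisson(lam)
    for j in range(1, n):
        ratio = alpha / np.sqrt(1.0 - alpha * alpha) if j == 1 else alpha
        lam_star = lam + ratio * (Y[:, j - 1] - lam)
        Y[:, j] = rng.poisson(lam_star)
    subjects = [
        Subject(y=Y[i], X=np.tile(X_subjects[i], (n, 1)), subject_id=i + 1)
        for i in range(m)
    ]
    ds = LongitudinalDataset(subjects, covariate_names=covariate_names)
    # generated data must satisfy the constraints at the generating values
    assert np.all(_slacks(ds, beta, alpha) > 0)
    return ds


def simulate_dataset(cfg: SimulationConfig,
                     rng: np.random.Generator) -> LongitudinalDataset:
    """Covariates plus counts for one replicate of the study design."""
    X = simulate_covariates(cfg, rng)
    return simulate_counts(X, cfg.beta, cfg.alpha, rng,
                           n_per_subject=cfg.n_per_subject,
                           covariate_names=cfg.covariate_names)
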