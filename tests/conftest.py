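import numpy as np
import pytest

from adpois import (LongitudinalDataset, SimulationConfig, Subject,
                    simulate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def one_subject_pair():
    """Single subject, two visits, unit means (X = intercept only)."""
    return LongitudinalDataset(
        [Subject(y=[0, 1], X=[[1.0], [1.0]], subject_id="s1")])


@pytest.fixture
def small_dataset():
    """Deterministic 20-subject dataset from the study design."""
    cfg = SimulationConfig(m=20, alpha=0.3)
    return simulate_dataset(cfg, np.random.default_rng(7))


def make_design_dataset(m=40, alpha=0.4, seed=0, n=4):
    cfg = SimulationConfig(m=m, alpha=alpha, n_per_subject=n)
    return cfg, simulate_dataset(cfg, np.random.default_rng(seed))


def random_feasible_instance(seed, m=8, n=4):
    """Small random dataset plus a random feasible parameter point."""
    from adpois import ModelParams, check_constraints

    rng = np.random.default_rng(seed)
    p = 3
    subjects = []
    for i in range(m):
        X = np.column_stack([np.ones(n), rng.normal(0, 0.5, size=(n, p - 1))])
        subjects.append(Subject(y=rng.poisson(2.0, size=n), X=X,
                                subject_id=i))
    data = LongitudinalDataset(subjects)
    for _ in range(100):
        beta = rng.normal(0, 0.4, size=p)
        alpha = rng.uniform(0.0, 0.6)
        params = ModelParams(beta, alpha)
        rep = check_constraints(data, params)
        if not rep.feasible:
            continue
        try:
            from adpois import log_likelihood
            log_likelihood(data, params)
        except Exception:
            continue
        return data, params
    raise RuntimeError("could not draw a feasible instance")
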