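import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import poisson

from adpois import (ConstraintError, InfeasiblePointError,
                    LongitudinalDataset, ModelParams, Subject, ValidationError,
                    alpha_bound, check_constraints, conditional_mean,
                    grad_log_likelihood, log_likelihood, marginal_mean,
                    marginal_sd)
from conftest import random_feasible_instance


class TestMarginalMean:
    def test_identity_case(self):
        assert marginal_mean([1, 0, 0, 0], [0, 0, 0, 0]) == 1.0

    def test_zero_beta(self, rng):
        x = rng.normal(size=5)
        assert marginal_mean(x, np.zeros(5)) == 1.0

    def test_study_design_row(self):
        # dot-product oracle: 0.4467 - 0.1659 + 0.0232*31 + 0.0258*28
        x = (1, 1, 31, 28)
        beta = (0.4467, -0.1659, 0.0232, 0.0258)
        expected = np.exp(np.dot(x, beta))
        assert marginal_mean(x, beta) == pytest.approx(expected, rel=1e-15)
        assert np.dot(x, beta) == pytest.approx(1.7224, abs=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            marginal_mean([1, 2], [1, 2, 3])


class TestMarginalSd:
    def test_first_visit(self):
        assert marginal_sd(4.0, 0.6, is_first_visit=True) == 2.0

    def test_alpha_zero_reduces_to_poisson(self):
        assert marginal_sd(4.0, 0.0, is_first_visit=False) == 2.0

    def test_overdispersed_later_visit(self):
        assert marginal_sd(4.0, 0.6, is_first_visit=False) == pytest.approx(
            2.5, rel=1e-12)  # sqrt(4 / 0.64)

    def test_alpha_out_of_range(self):
        with pytest.raises(ConstraintError):
            marginal_sd(4.0, 1.0, is_first_visit=False)


class TestConditionalMean:
    def test_alpha_zero(self):
        assert conditional_mean(2.0, 5.0, 1.0, 1.0, 7, 0.0) == 2.0

    def test_previous_at_its_mean(self):
        assert conditional_mean(2.0, 4.0, 1.5, 2.0, 4, 0.5) == 2.0

    def test_unit_sd_ratio(self):
        # lam_cur = lam_prev = 2, alpha = 0.5, y_prev = 4
        assert conditional_mean(2.0, 2.0, 1.0, 1.0, 4, 0.5) == 3.0

    def test_second_visit_ratio(self):
        # lam1 = lam2 = 2, alpha = 0.5: sd ratio = 1/sqrt(0.75); y_prev = 0
        sd1 = marginal_sd(2.0, 0.5, True)
        sd2 = marginal_sd(2.0, 0.5, False)
        got = conditional_mean(2.0, 2.0, sd2, sd1, 0, 0.5)
        assert got == pytest.approx(2 - 0.5 * 2 / np.sqrt(0.75), rel=1e-12)
        assert got == pytest.approx(0.8453, abs=5e-5)


def _constant_mean_dataset(n=4, log_mean=0.0):
    return LongitudinalDataset(
        [Subject(y=np.zeros(n, dtype=int), X=np.full((n, 1), 1.0))]), \
        np.array([log_mean])


class TestConstraints:
    def test_alpha_zero_always_feasible(self, small_dataset):
        rep = check_constraints(small_dataset,
                                ModelParams(np.zeros(4), 0.0))
        assert rep.feasible
        lam = np.exp(small_dataset.X @ np.zeros(4))
        assert np.allclose(rep.slacks, lam[small_dataset.cur_idx])

    @pytest.mark.parametrize("log_mean", [0.0, 1.3, -2.0])
    def test_equal_means_bound_is_inverse_sqrt2(self, log_mean):
        data, beta = _constant_mean_dataset(log_mean=log_mean)
        assert alpha_bound(data, beta) == pytest.approx(1 / np.sqrt(2),
                                                        abs=1e-9)

    def test_two_visit_unequal_means_bound(self):
        # means (1, 4): bound solves a/sqrt(1-a^2) = 2  =>  a = 2/sqrt(5)
        data = LongitudinalDataset(
            [Subject(y=[0, 0], X=[[1, 0], [1, np.log(4)]])])
        beta = np.array([0.0, 1.0])
        assert alpha_bound(data, beta) == pytest.approx(2 / np.sqrt(5),
                                                        abs=1e-9)

    def test_bound_matches_root_finding_oracle(self):
        # independent oracle: brentq on the analytic minimal-slack function
        data = LongitudinalDataset(
            [Subject(y=[0, 0, 0], X=[[1, 0], [1, 1], [1, 0.5]])])
        beta = np.array([0.1, 0.7])
        lam = np.exp(data.X @ beta)

        def min_slack(a):
            s2 = lam[1] - a / np.sqrt(1 - a * a) * np.sqrt(lam[0] * lam[1])
            s3 = lam[2] - a * np.sqrt(lam[1] * lam[2])
            return min(s2, s3)

        expected = brentq(min_slack, 1e-12, 1 - 1e-12, xtol=1e-12)
        assert alpha_bound(data, beta) == pytest.approx(expected, abs=1e-8)

    def test_bound_monotone_in_mean_ratio(self):
        # increasing lam1/lam2 tightens the j=2 constraint
        bounds = []
        for log_l1 in (0.0, 0.5, 1.0, 2.0):
            data = LongitudinalDataset(
                [Subject(y=[0, 0], X=[[1, 1], [1, 0]])])
            bounds.append(alpha_bound(data, np.array([0.0, log_l1])))
        assert all(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:]))

    def test_feasibility_flag(self, small_dataset):
        beta = np.zeros(4)
        ok = check_constraints(small_dataset, ModelParams(beta, 0.5))
        bad = check_constraints(small_dataset, ModelParams(beta, 0.8))
        assert ok.feasible and not bad.feasible

    def test_single_visit_dataset_bound_is_one(self):
        data = LongitudinalDataset([Subject(y=[3], X=[[1.0]])])
        assert alpha_bound(data, np.zeros(1)) == 1.0


class TestLogLikelihood:
    def test_single_zero_count(self):
        data = LongitudinalDataset([Subject(y=[0], X=[[1.0]])])
        assert log_likelihood(data, ModelParams([0.0], 0.0)) == \
            pytest.approx(-1.0, abs=1e-12)

    def test_alpha_zero_is_poisson(self, one_subject_pair):
        assert log_likelihood(one_subject_pair, ModelParams([0.0], 0.0)) \
            == pytest.approx(-2.0, abs=1e-12)

    def test_hand_evaluated_pair(self, one_subject_pair):
        lam_star = 1 - 0.5 / np.sqrt(0.75)
        expected = -1.0 + np.log(lam_star) - lam_star
        got = log_likelihood(one_subject_pair, ModelParams([0.0], 0.5))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-2.2839, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_alpha_zero_matches_independent_poisson(self, seed):
        # library oracle: sum of scipy poisson log-pmfs
        data, params = random_feasible_instance(seed)
        params0 = ModelParams(params.beta, 0.0)
        lam = np.exp(data.X @ params0.beta)
        expected = poisson.logpmf(data.y, lam).sum()
        assert log_likelihood(data, params0) == pytest.approx(
            expected, rel=1e-13)

    def test_infeasible_point_raises(self):
        data = LongitudinalDataset(
            [Subject(y=[9, 0, 0], X=np.ones((3, 1)))])
        # large previous count with lam* driven negative is impossible for
        # alpha >= 0; force it with a negative alpha and y_prev > lam
        with pytest.raises(InfeasiblePointError):
            log_likelihood(data, ModelParams([0.0], -0.6))

    def test_subject_permutation_invariance(self, small_dataset, rng):
        params = ModelParams(np.array([0.3, -0.1, 0.01, 0.01]), 0.2)
        perm = rng.permutation(small_dataset.m)
        shuffled = LongitudinalDataset(
            [small_dataset.subjects[i] for i in perm])
        assert log_likelihood(shuffled, params) == pytest.approx(
            log_likelihood(small_dataset, params), rel=1e-14)


class TestGradient:
    def test_alpha_zero_is_poisson_score(self, small_dataset):
        beta = np.array([0.2, 0.05, 0.01, 0.02])
        g = grad_log_likelihood(small_dataset, ModelParams(beta, 0.0))
        lam = np.exp(small_dataset.X @ beta)
        score = (small_dataset.y - lam) @ small_dataset.X
        assert np.allclose(g[:-1], score, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        data, params = random_feasible_instance(seed)
        g = grad_log_likelihood(data, params)
        theta = params.theta
        fd = np.empty_like(g)
        for k in range(theta.size):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd[k] = (log_likelihood(data, ModelParams.from_theta(tp))
                     - log_likelihood(data, ModelParams.from_theta(tm))) \
                / (2 * h)
        assert np.max(np.abs(g - fd) / (np.abs(fd) + 1e-8)) < 1e-6


class TestValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            Subject(y=[-1, 2], X=np.ones((2, 1)))

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValidationError):
            Subject(y=[1.5, 2], X=np.ones((2, 1)))

    def test_inconsistent_covariate_dims(self):
        s1 = Subject(y=[1], X=[[1.0, 2.0]])
        s2 = Subject(y=[1], X=[[1.0]])
        with pytest.raises(ValidationError):
            LongitudinalDataset([s1, s2])

    def test_alpha_outside_open_interval(self):
        with pytest.raises(ConstraintError):
            ModelParams([0.0], 1.0)

    def test_single_visit_subjects_accepted(self):
        data = LongitudinalDataset(
            [Subject(y=[2], X=[[1.0]]), Subject(y=[1, 3], X=np.ones((2, 1)))])
        assert data.n_pairs == 1
        assert np.isfinite(log_likelihood(data, ModelParams([0.5], 0.1)))
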