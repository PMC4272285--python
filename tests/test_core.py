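"""Core model: moment matching, the cdf of Q, both objective functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from surveydesign import (
    DesignProblem,
    InfeasibleDesignError,
    RatePrior,
    SatisficingTarget,
    ScaledProblem,
    expected_q,
    moment_match,
    prob_target,
    q_cdf,
    scale_problem,
    survey_time,
)
from surveydesign.core import _expected_q_from_moments


class TestTypes:
    def test_rate_prior_cv_consistency(self):
        rate = RatePrior(mu=0.67, sigma=1.675)
        assert rate.theta == pytest.approx(2.5, rel=1e-12)
        rate2 = RatePrior.from_cv(mu=0.67, theta=2.5)
        assert rate2.sigma == pytest.approx(1.675, rel=1e-12)

    @pytest.mark.parametrize("mu,sigma", [(0.0, 1.0), (-1.0, 1.0), (1.0, -0.1)])
    def test_invalid_rate_rejected(self, mu, sigma):
        with pytest.raises(ValueError):
            RatePrior(mu=mu, sigma=sigma)

    def test_satisficing_target_cloglog(self):
        t = SatisficingTarget(Q_c=0.05)
        assert t.X_c == pytest.approx(math.log(-math.log(0.05)))
        assert SatisficingTarget.from_detection_prob(0.95).Q_c == pytest.approx(0.05)

    @pytest.mark.parametrize("qc", [0.0, 1.0, -0.5, 1.5])
    def test_target_open_interval(self, qc):
        with pytest.raises(ValueError):
            SatisficingTarget(Q_c=qc)


class TestScaling:
    def test_scale_problem_frog(self):
        sp = scale_problem(
            DesignProblem(B=10.0, c=1.0, rate=RatePrior(mu=0.67, sigma=1.675))
        )
        assert sp.Bp == pytest.approx(6.7)
        assert sp.cp == pytest.approx(0.67)
        assert sp.theta == pytest.approx(2.5)

    def test_scale_problem_plants(self):
        sp = scale_problem(
            DesignProblem(B=15.0, c=0.25, rate=RatePrior.from_cv(0.56, 1.0))
        )
        assert sp.Bp == pytest.approx(8.4)
        assert sp.cp == pytest.approx(0.14)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            DesignProblem(B=10, c=1, rate=RatePrior(mu=0.0, sigma=1.0))

    @pytest.mark.parametrize(
        "n,B,c,expect", [(4, 10, 1, 1.5), (1, 10, 1, 9.0), (3, 6, 1, 1.0)]
    )
    def test_survey_time(self, n, B, c, expect):
        assert survey_time(n, B, c) == pytest.approx(expect)

    def test_survey_time_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            survey_time(10, 10, 1)


class TestMomentMatch:
    def test_printed_formulas(self):
        mm = moment_match(1, ScaledProblem(Bp=2, cp=0.5, theta=1.0))
        assert mm.mu_A == pytest.approx(1.5)
        assert mm.v == pytest.approx(math.log(2.0))
        assert mm.m == pytest.approx(math.log(1.5) - math.log(2.0) / 2)

    def test_degenerate_theta_zero(self):
        mm = moment_match(3, ScaledProblem(Bp=6, cp=1.0, theta=0.0))
        assert mm.v == 0.0
        assert mm.m == pytest.approx(math.log(3.0))
        assert mm.sigma_A == 0.0

    def test_infeasible_raises(self):
        with pytest.raises(InfeasibleDesignError):
            moment_match(20, ScaledProblem(Bp=10, cp=0.5, theta=1.0))

    @given(
        n=st.integers(1, 30),
        Bp=st.floats(0.5, 50),
        cp=st.floats(0.0, 1.5),
        theta=st.floats(0.01, 4.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_lognormal_moment_fidelity(self, n, Bp, cp, theta):
        """The matched lognormal reproduces mean and variance of A exactly."""
        if Bp - n * cp <= 1e-6:
            return
        mm = moment_match(n, ScaledProblem(Bp=Bp, cp=cp, theta=theta))
        mean = math.exp(mm.m + mm.v / 2)
        var = (math.exp(mm.v) - 1) * math.exp(2 * mm.m + mm.v)
        assert mean == pytest.approx(mm.mu_A, rel=1e-10)
        assert var == pytest.approx(mm.sigma_A**2, rel=1e-10)

    def test_moment_fidelity_by_sampling(self, rng):
        """exp(m + v/2) equals mu_A: checked by brute-force lognormal draws."""
        mm = moment_match(4, ScaledProblem(Bp=10, cp=0.5, theta=1.5))
        draws = rng.lognormal(mm.m, math.sqrt(mm.v), size=10**6)
        assert mm.mu_A == pytest.approx(8.0)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 8.0) < 3 * se


class TestQcdf:
    def setup_method(self):
        self.mm = moment_match(1, ScaledProblem(Bp=2, cp=0.5, theta=1.0))

    def test_median_maps_to_half(self):
        q_med = math.exp(-math.exp(self.mm.m))
        assert q_cdf(q_med, self.mm) == pytest.approx(0.5, abs=1e-12)

    def test_limits_and_monotonicity(self):
        qs = np.concatenate([[1e-30], np.linspace(1e-9, 1 - 1e-9, 200)])
        vals = q_cdf(qs, self.mm)
        assert vals[0] < 1e-6 and vals[-1] > 1 - 1e-6
        assert np.all(np.diff(vals) >= 0)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.1])
    def test_domain_error(self, q):
        with pytest.raises(ValueError):
            q_cdf(q, self.mm)

    def test_against_empirical_cdf(self, rng):
        """Sup-distance to the empirical cdf of exp(-A), A lognormal(m, v)."""
        draws = np.exp(-rng.lognormal(self.mm.m, math.sqrt(self.mm.v), 10**6))
        qs = np.linspace(0.01, 0.99, 99)
        emp = np.searchsorted(np.sort(draws), qs) / draws.size
        assert np.max(np.abs(q_cdf(qs, self.mm) - emp)) < 0.005

    def test_degenerate_step(self):
        mm0 = moment_match(2, ScaledProblem(Bp=4, cp=0.5, theta=0.0))
        q_step = math.exp(-math.exp(mm0.m))
        assert q_cdf(q_step * 0.99, mm0) == 0.0
        assert q_cdf(min(q_step * 1.01, 0.999999), mm0) == 1.0


class TestExpectedQ:
    def test_theta_zero_closed_form(self):
        sp = ScaledProblem(Bp=3, cp=0.5, theta=0.0)
        assert expected_q(1, sp) == pytest.approx(math.exp(-2.5), rel=0, abs=0)

    def test_frog_detection_probability(self, frog_low):
        assert 1 - expected_q(3, frog_low) == pytest.approx(0.83, abs=0.005)

    def test_quadrature_matches_adaptive(self):
        """Gauss-Hermite agrees with adaptive quadrature to 1e-10."""
        for m, v in [(0.0589, 0.6931), (2.0, 0.1), (-1.0, 2.0), (1.5, 1.0)]:
            f = lambda x: math.exp(-math.exp(x)) * math.exp(
                -((x - m) ** 2) / (2 * v)
            ) / math.sqrt(2 * math.pi * v)
            ref, _ = integrate.quad(f, m - 14 * math.sqrt(v),
                                    m + 14 * math.sqrt(v), limit=300,
                                    epsabs=1e-13, epsrel=1e-13)
            assert _expected_q_from_moments(m, v) == pytest.approx(
                ref, abs=1e-10
            )

    def test_monte_carlo_oracle(self, rng):
        """Quadrature matches the sampled mean of exp(-A), A lognormal(m, v)."""
        sp = ScaledProblem(Bp=10, cp=0.5, theta=1.5)
        mm = moment_match(4, sp)
        draws = np.exp(-rng.lognormal(mm.m, math.sqrt(mm.v), 10**7))
        se = draws.std() / math.sqrt(draws.size)
        assert abs(expected_q(4, sp) - draws.mean()) < 3 * se

    def test_decreasing_in_budget(self):
        vals = [
            expected_q(3, ScaledProblem(Bp=b, cp=0.5, theta=1.5))
            for b in np.linspace(2, 20, 30)
        ]
        assert np.all(np.diff(vals) < 0)

    @given(
        k=st.floats(0.1, 10),
        mu=st.floats(0.1, 3.0),
        theta=st.floats(0.0, 3.0),
        n=st.integers(1, 6),
    )
    @settings(max_examples=150, deadline=None)
    def test_scale_invariance(self, k, mu, theta, n):
        """Only (B', c', theta) matter: rescaling rate and times is a no-op."""
        B, c = 12.0, 1.0
        p1 = DesignProblem(B=B, c=c, rate=RatePrior.from_cv(mu, theta))
        p2 = DesignProblem(B=B / k, c=c / k, rate=RatePrior.from_cv(mu * k, theta))
        sp1, sp2 = scale_problem(p1), scale_problem(p2)
        if sp1.Bp - n * sp1.cp <= 1e-9:
            return
        assert expected_q(n, sp1) == pytest.approx(expected_q(n, sp2), abs=1e-9)
        target = SatisficingTarget(0.05)
        assert prob_target(n, sp1, target) == pytest.approx(
            prob_target(n, sp2, target), abs=1e-9
        )


class TestProbTarget:
    def test_half_at_threshold(self):
        # choose Bp so that m equals X_c exactly
        theta, n, cp = 1.0, 2, 0.5
        v = math.log1p(theta**2 / n)
        target = SatisficingTarget(0.05)
        mu_A = math.exp(target.X_c + v / 2)
        sp = ScaledProblem(Bp=mu_A + n * cp, cp=cp, theta=theta)
        assert prob_target(n, sp, target) == pytest.approx(0.5, abs=1e-12)

    def test_theta_zero_indicator(self):
        target = SatisficingTarget(0.05)
        hi = ScaledProblem(Bp=5.0, cp=0.5, theta=0.0)   # mu_A = 4.5 > 3.0
        lo = ScaledProblem(Bp=2.0, cp=0.5, theta=0.0)   # mu_A = 1.5 < 3.0
        assert prob_target(1, hi, target) == 1.0
        assert prob_target(1, lo, target) == 0.0

    def test_monte_carlo_oracle(self, rng):
        sp = ScaledProblem(Bp=10, cp=0.5, theta=1.5)
        mm = moment_match(4, sp)
        target = SatisficingTarget(0.05)
        draws = np.exp(-rng.lognormal(mm.m, math.sqrt(mm.v), 10**7))
        p_hat = np.mean(draws < 0.05)
        se = math.sqrt(p_hat * (1 - p_hat) / draws.size)
        assert abs(prob_target(4, sp, target) - p_hat) < 3 * se
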