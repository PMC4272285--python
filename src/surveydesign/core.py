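"""Probabilistic engine for survey design under stochastic detectability.

A present species is detected as a Poisson process with rate ``lambda_i``
during survey ``i``; the rates vary stochastically between surveys (weather,
observer, season) and are modelled as lognormal random variables with mean
``mu`` and standard deviation ``sigma``. With ``n`` equal-length surveys of
search time ``t`` each, the total expected number of detections is
``A = t * sum(lambda_i)`` and the probability of failing to detect the
species over the whole survey period is ``Q = exp(-A)``.

``A`` is approximated as lognormal by moment matching (Fenton–Wilkinson):
``X = ln(A)`` is normal with mean ``m`` and variance ``v`` chosen so the
lognormal mean and variance equal ``mu_A = n*mu*t`` and
``sigma_A^2 = n*sigma^2*t^2`` exactly.  Everything downstream depends only
on the dimensionless trio (scaled budget ``B' = B*mu``, scaled fixed cost
``c' = c*mu``, coefficient of variation ``theta = sigma/mu``).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy import special

__all__ = [
    "InfeasibleDesignError",
    "RatePrior",
    "DesignProblem",
    "ScaledProblem",
    "SurveyDesign",
    "MomentMatch",
    "SatisficingTarget",
    "DesignEvaluation",
    "scale_problem",
    "survey_time",
    "feasible_n_max",
    "moment_match",
    "q_cdf",
    "expected_q",
    "prob_target",
    "evaluate_design",
]


class InfeasibleDesignError(ValueError):
    """Raised when a design leaves no positive search time (t = B/n - c <= 0)."""


# 128-node Gauss-Hermite rule (probabilists' weighting) used for E[Q];
# the integrand exp(-exp(x)) is entire, so convergence is spectral.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(128)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class RatePrior:
    """Mean and s.d. of the stochastic detection rate (detections per unit time)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"detection rate mu must be > 0, got {self.mu}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def theta(self) -> float:
        """Coefficient of variation sigma/mu."""
        return self.sigma / self.mu

    @classmethod
    def from_cv(cls, mu: float, theta: float) -> "RatePrior":
        if theta < 0:
            raise ValueError(f"theta must be >= 0, got {theta}")
        return cls(mu=mu, sigma=theta * mu)

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma, "theta": self.theta}


@dataclass(frozen=True)
class DesignProblem:
    """Total time budget B, per-survey fixed (non-search) cost c, and rate prior."""

    B: float
    c: float
    rate: RatePrior

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError(f"budget B must be > 0, got {self.B}")
        if self.c < 0:
            raise ValueError(f"fixed cost c must be >= 0, got {self.c}")
        if self.B <= self.c:
            raise InfeasibleDesignError(
                f"budget B={self.B} must exceed the fixed cost c={self.c} "
                "for even a single survey to have search time"
            )


@dataclass(frozen=True)
class ScaledProblem:
    """Dimensionless problem: B' = B*mu, c' = c*mu, theta = sigma/mu."""

    Bp: float
    cp: float
    theta: float

    def __post_init__(self) -> None:
        if not self.Bp > 0:
            raise ValueError(f"scaled budget must be > 0, got {self.Bp}")
        if self.cp < 0:
            raise ValueError(f"scaled fixed cost must be >= 0, got {self.cp}")
        if self.Bp <= self.cp:
            raise InfeasibleDesignError(
                f"scaled budget {self.Bp} must exceed scaled fixed cost {self.cp}"
            )
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")


@dataclass(frozen=True)
class SurveyDesign:
    """A candidate design: n equal surveys of search time t each."""

    n: int
    t: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.n != int(self.n):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not self.t > 0:
            raise InfeasibleDesignError(f"search time t must be > 0, got {self.t}")


@dataclass(frozen=True)
class MomentMatch:
    """Lognormal parameters for the total expected detections A.

    mu_A, sigma_A are the exact mean and s.d. of A; (m, v) are the mean and
    variance of X = ln(A) such that the lognormal reproduces them exactly.
    v = 0 marks the degenerate point-mass case (theta = 0).
    """

    mu_A: float
    sigma_A: float
    m: float
    v: float


@dataclass(frozen=True)
class SatisficingTarget:
    """Acceptable probability of failed detection Q_c, with X_c = ln(-ln Q_c)."""

    Q_c: float

    def __post_init__(self) -> None:
        if not 0.0 < self.Q_c < 1.0:
            raise ValueError(f"Q_c must lie in (0, 1), got {self.Q_c}")

    @property
    def X_c(self) -> float:
        """Complementary log-log transform of Q_c."""
        return math.log(-math.log(self.Q_c))

    @classmethod
    def from_detection_prob(cls, p: float) -> "SatisficingTarget":
        """Target expressed as a required detection probability p (Q_c = 1 - p)."""
        if not 0.0 < p < 1.0:
            raise ValueError(f"detection probability must lie in (0, 1), got {p}")
        return cls(Q_c=1.0 - p)


@dataclass(frozen=True)
class DesignEvaluation:
    """Both objective functions evaluated at a fixed design."""

    n: int
    t: float
    expected_q: float
    objective_value: float
    prob_below_qc: Optional[float] = None

    @property
    def detection_prob(self) -> float:
        """Expected probability of detecting the species at least once, 1 - E[Q]."""
        return 1.0 - self.expected_q

    def to_dict(self) -> dict:
        return asdict(self)


def scale_problem(problem: DesignProblem) -> ScaledProblem:
    """Express a design problem in units of mean time-to-first-detection 1/mu."""
    mu = problem.rate.mu
    return ScaledProblem(Bp=problem.B * mu, cp=problem.c * mu, theta=problem.rate.theta)


def survey_time(n: int, B: float, c: float) -> float:
    """Search time per survey, t = B/n - c, under the budget constraint B = n(c+t)."""
    if n < 1 or n != int(n):
        raise ValueError(f"n must be a positive integer, got {n}")
    t = B / n - c
    if t <= 0:
        raise InfeasibleDesignError(
            f"n={n} surveys leave no search time (B/n - c = {t:.6g} <= 0); "
            f"need n < B/c = {B / c if c > 0 else math.inf:.6g}"
        )
    return t


def feasible_n_max(Bp: float, cp: float, cap: int = 10_000) -> int:
    """Largest n with strictly positive search time; `cap` bounds the c=0 case."""
    if cp <= 0:
        return cap
    n = math.ceil(Bp / cp) - 1
    while n >= 1 and Bp / n - cp <= 0:
        n -= 1
    if n < 1:
        raise InfeasibleDesignError(
            f"no feasible design: scaled budget {Bp} <= scaled fixed cost {cp}"
        )
    return min(n, cap)


def moment_match(n: int, sp: ScaledProblem) -> MomentMatch:
    """Lognormal moment match for A at a feasible n, in scaled form.

    mu_A = B' - n c' (total scaled search time), sigma_A = theta * mu_A / sqrt(n).
    """
    if n < 1 or n != int(n):
        raise ValueError(f"n must be a positive integer, got {n}")
    mu_A = sp.Bp - n * sp.cp
    if mu_A <= 0:
        raise InfeasibleDesignError(
            f"n={n} infeasible: B' - n c' = {mu_A:.6g} <= 0"
        )
    if sp.theta == 0:
        return MomentMatch(mu_A=mu_A, sigma_A=0.0, m=math.log(mu_A), v=0.0)
    ratio2 = sp.theta**2 / n  # (sigma_A / mu_A)^2
    v = math.log1p(ratio2)
    m = math.log(mu_A) - v / 2.0
    return MomentMatch(mu_A=mu_A, sigma_A=mu_A * math.sqrt(ratio2), m=m, v=v)


def q_cdf(q, mm: MomentMatch):
    """Pr(Q <= q) for Q = exp(-A), A lognormal(m, v).

    Since Q < q iff X = ln(A) > ln(-ln q), the cdf is
    1 - Phi((ln(-ln q) - m)/sqrt(v)).  Accepts scalar or array q in (0, 1).
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr <= 0.0) or np.any(q_arr >= 1.0):
        raise ValueError("q must lie strictly inside (0, 1)")
    w = np.log(-np.log(q_arr))
    if mm.v == 0.0:
        out = np.where(w < mm.m, 1.0, np.where(w > mm.m, 0.0, 0.5))
    else:
        out = special.ndtr(-(w - mm.m) / math.sqrt(mm.v))
    return float(out) if np.isscalar(q) else out


def _expected_q_from_moments(m: float, v: float) -> float:
    # E[exp(-exp(X))], X ~ N(m, v), by 128-node Gauss-Hermite on the X scale
    x = m + math.sqrt(v) * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * np.exp(-np.exp(x))))


def expected_q(n: int, sp: ScaledProblem) -> float:
    """Expected probability of failed detection E[Q] for n equal surveys.

    Deterministic quadrature of E[exp(-exp(X))] with X ~ N(m, v); exact
    closed form exp(-(B' - n c')) in the degenerate theta = 0 case.
    """
    mm = moment_match(n, sp)
    if mm.v == 0.0:
        return math.exp(-mm.mu_A)
    return _expected_q_from_moments(mm.m, mm.v)


def prob_target(n: int, sp: ScaledProblem, target: SatisficingTarget) -> float:
    """Pr(Q < Q_c) = Phi((m - X_c)/sqrt(v)); indicator in the theta = 0 case."""
    mm = moment_match(n, sp)
    if mm.v == 0.0:
        return 1.0 if mm.mu_A > -math.log(target.Q_c) else 0.0
    return float(special.ndtr((mm.m - target.X_c) / math.sqrt(mm.v)))


def evaluate_design(
    n: int,
    sp: ScaledProblem,
    target: Optional[SatisficingTarget] = None,
    objective: str = "expected_detection",
) -> DesignEvaluation:
    """Evaluate both objectives at a fixed n (t reported in scaled time units)."""
    t = survey_time(n, sp.Bp, sp.cp)
    eq = expected_q(n, sp)
    pb = prob_target(n, sp, target) if target is not None else None
    if objective == "expected_detection":
        obj = 1.0 - eq
    elif objective == "satisficing":
        if pb is None:
            raise ValueError("satisficing objective requires a SatisficingTarget")
        obj = pb
    else:
        raise ValueError(f"unknown objective {objective!r}")
    return DesignEvaluation(
        n=n, t=t, expected_q=eq, objective_value=obj, prob_below_qc=pb
    )
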