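"""Optimal integer number of surveys for both design objectives.

Exact optima come from exhaustive enumeration over the feasible range
``n = 1 .. n_max`` (ground truth; ties broken toward smaller n, since fewer
trips at equal performance is operationally cheaper).  Closed-form
approximations give the same answers at a glance:

* expected-detection objective — the positive root of
  ``2 n^2 + 5 theta^2 n - 3 theta^2 (B/c) = 0``, obtained by a Laplace-type
  argument (approximate E[Q] by exp(-mode(A)) and maximize the mode
  ``mu_A (1 + theta^2/n)^(-3/2)`` over continuous n).  It depends on the
  budget-to-cost ratio B/c and the coefficient of variation only.
* satisficing objective — for small theta the stationarity condition of
  Pr(Q < Q_c) collapses to ``ln(mu_A) - X_c = 2 n c'/mu_A``, solved in
  closed form with the Lambert W function:
  ``n = (B'/c') (1 - 2 / W(2 B' e^(2 - X_c)))``.  The scaled fixed cost
  enters purely as a 1/c' scaling, so doubling c' halves the answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Set

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import special

from .core import (
    DesignEvaluation,
    InfeasibleDesignError,
    SatisficingTarget,
    ScaledProblem,
    evaluate_design,
    feasible_n_max,
)

__all__ = [
    "NoInteriorOptimumError",
    "OptimizationResult",
    "optimal_n_expected",
    "optimal_n_satisficing",
    "approx_n_expected",
    "approx_n_satisficing",
    "solve_implicit_satisficing",
    "near_optimal_set",
    "design_table",
]

Objective = Literal["expected_detection", "satisficing"]


class NoInteriorOptimumError(RuntimeError):
    """The continuous relaxation has no interior stationary maximum."""


@dataclass(frozen=True)
class OptimizationResult:
    best: DesignEvaluation
    all_evaluations: List[DesignEvaluation]
    objective: Objective

    @property
    def n_opt(self) -> int:
        return self.best.n


def _require_optimizable(sp: ScaledProblem) -> int:
    if sp.cp <= 0:
        raise ValueError(
            "optimization requires a strictly positive fixed cost; with c = 0 "
            "the expected-detection objective improves without bound in n"
        )
    return feasible_n_max(sp.Bp, sp.cp)


def optimal_n_expected(sp: ScaledProblem) -> OptimizationResult:
    """Minimize E[Q] by exhaustive enumeration over feasible integer n."""
    n_max = _require_optimizable(sp)
    evals = [
        evaluate_design(n, sp, objective="expected_detection")
        for n in range(1, n_max + 1)
    ]
    best = max(evals, key=lambda e: (e.objective_value, -e.n))
    return OptimizationResult(best=best, all_evaluations=evals,
                              objective="expected_detection")


def optimal_n_satisficing(
    sp: ScaledProblem, target: SatisficingTarget
) -> OptimizationResult:
    """Maximize Pr(Q < Q_c) by exhaustive enumeration over feasible integer n."""
    n_max = _require_optimizable(sp)
    evals = [
        evaluate_design(n, sp, target=target, objective="satisficing")
        for n in range(1, n_max + 1)
    ]
    best = max(evals, key=lambda e: (e.objective_value, -e.n))
    return OptimizationResult(best=best, all_evaluations=evals,
                              objective="satisficing")


def approx_n_expected_continuous(ratio: float, theta: float) -> float:
    """Continuous closed-form optimum for objective 1; ratio = B/c."""
    if ratio <= 1:
        raise InfeasibleDesignError(f"B/c must exceed 1, got {ratio}")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if theta == 0:
        return 1.0
    t2 = theta * theta
    return (math.sqrt(25.0 * t2 * t2 + 24.0 * t2 * ratio) - 5.0 * t2) / 4.0


def approx_n_expected(B: float, c: float, theta: float) -> int:
    """Closed-form approximate optimal n for the expected-detection objective.

    Depends on (B/c, theta) only; rounded to the nearest feasible integer
    (the signature carries no rate, so the exact objective cannot be used to
    arbitrate floor vs ceil).
    """
    if not (B > c > 0):
        raise InfeasibleDesignError(f"need B > c > 0, got B={B}, c={c}")
    ratio = B / c
    n_cont = approx_n_expected_continuous(ratio, theta)
    n_hi = math.ceil(ratio) - 1 if ratio == math.ceil(ratio) else math.floor(ratio)
    while n_hi >= 1 and B / n_hi - c <= 0:
        n_hi -= 1
    n = int(math.floor(n_cont + 0.5))
    return max(1, min(n, max(n_hi, 1)))


def approx_n_satisficing_continuous(Bp: float, cp: float, Q_c: float) -> float:
    """Continuous small-theta optimum for the satisficing objective (Lambert W)."""
    if not (Bp > cp > 0):
        raise InfeasibleDesignError(f"need B' > c' > 0, got B'={Bp}, c'={cp}")
    X_c = math.log(-math.log(Q_c))
    w = special.lambertw(2.0 * Bp * math.exp(2.0 - X_c)).real
    return (Bp / cp) * (1.0 - 2.0 / w)


def approx_n_satisficing(sp: ScaledProblem, target: SatisficingTarget) -> int:
    """Closed-form approximate optimal n for the satisficing objective.

    The continuous value is rounded by evaluating the exact Pr(Q < Q_c) at
    its floor and ceiling and keeping the better feasible one.
    """
    n_cont = approx_n_satisficing_continuous(sp.Bp, sp.cp, target.Q_c)
    n_max = feasible_n_max(sp.Bp, sp.cp)
    lo = max(1, min(int(math.floor(n_cont)), n_max))
    hi = max(1, min(int(math.ceil(n_cont)), n_max))
    if lo == hi:
        return lo
    # arbitrate on the normal-score scale (m - X_c)/sqrt(v), which orders
    # designs identically to Pr(Q < Q_c) but never saturates to a 1.0 tie
    return max(
        (lo, hi), key=lambda n: (_continuous_satisficing_score(n, sp, target), -n)
    )


def _continuous_satisficing_score(n: float, sp: ScaledProblem,
                                  target: SatisficingTarget) -> float:
    # G(n) = (m - X_c)/sqrt(v) for continuous n; Pr(Q < Q_c) = Phi(G)
    mu_A = sp.Bp - n * sp.cp
    if mu_A <= 0 or n <= 0:
        return -math.inf
    v = math.log1p(sp.theta**2 / n)
    m = math.log(mu_A) - v / 2.0
    return (m - target.X_c) / math.sqrt(v)


def _satisficing_score_derivative(n: float, sp: ScaledProblem,
                                  target: SatisficingTarget) -> float:
    # d/dn of G(n) = (m - X_c)/sqrt(v), continuous n; zero iff
    # 2 v m' = (m - X_c) v'
    mu_A = sp.Bp - n * sp.cp
    t2 = sp.theta**2
    v = math.log1p(t2 / n)
    m = math.log(mu_A) - v / 2.0
    dv = -t2 / (n * (n + t2))
    dm = -sp.cp / mu_A - dv / 2.0
    return dm * v - (m - target.X_c) * dv / 2.0  # proportional to G' * v^(3/2)


def solve_implicit_satisficing(
    sp: ScaledProblem, target: SatisficingTarget, tol: float = 1e-8
) -> float:
    """Continuous-n root of the satisficing stationarity condition.

    Solves 2 v dm/dn = (m - X_c) dv/dn on (0, n_max + 1) by bracketed root
    finding.  The enumeration optimum lies at the floor or ceiling of this
    root whenever the root is an interior local maximum of Pr(Q < Q_c).
    """
    if sp.theta == 0:
        raise ValueError(
            "degenerate case theta = 0: Pr(Q < Q_c) is an indicator and the "
            "continuous relaxation has no interior stationary point"
        )
    n_max = _require_optimizable(sp)
    eps = 1e-9
    lo, hi = eps, min(n_max + 1.0, sp.Bp / sp.cp - eps)
    grid = np.linspace(lo, hi, 512)
    vals = np.array([
        _satisficing_score_derivative(n, sp, target) for n in grid
    ])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    # keep only downward crossings (local maxima of the objective)
    for i in sign_change:
        if vals[i] > 0 >= vals[i + 1]:
            root = sp_optimize.brentq(
                _satisficing_score_derivative, grid[i], grid[i + 1],
                args=(sp, target), xtol=tol,
            )
            return float(root)
    raise NoInteriorOptimumError(
        "no interior stationary maximum in (0, n_max + 1); the optimum is at "
        "the boundary (n = 1 or n = n_max)"
    )


def near_optimal_set(
    sp: ScaledProblem,
    objective: Objective = "expected_detection",
    delta: float = 0.01,
    target: Optional[SatisficingTarget] = None,
) -> Set[int]:
    """All feasible n whose objective value is within delta of the optimum."""
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    if objective == "expected_detection":
        result = optimal_n_expected(sp)
    elif objective == "satisficing":
        if target is None:
            raise ValueError("satisficing objective requires a target")
        result = optimal_n_satisficing(sp, target)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    best_val = result.best.objective_value
    return {
        e.n for e in result.all_evaluations
        if best_val - e.objective_value <= delta
    }


def design_table(result: OptimizationResult) -> pd.DataFrame:
    """Tabulate an optimization run (columns mirror the CSV export contract)."""
    rows = []
    for e in result.all_evaluations:
        rows.append({
            "n": e.n,
            "t": e.t,
            "expected_Q": e.expected_q,
            "prob_below_Qc": e.prob_below_qc if e.prob_below_qc is not None
            else float("nan"),
            "objective_value": e.objective_value,
            "is_optimal": e.n == result.best.n,
        })
    return pd.DataFrame(rows)
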