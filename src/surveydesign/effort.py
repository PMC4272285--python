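"""Minimum survey-effort protocols.

Given a per-survey scaled fixed cost ``c'`` and rate variability ``theta``,
these routines find the smallest scaled budget ``B'`` whose *best* design
(number of surveys re-optimized at every budget) meets a required level of
performance: either a minimum expected detection probability ``1 - E[Q]``
or a minimum assurance ``Pr(Q < Q_c) >= P_c``.  Both requirements are
monotone in the budget once the inner integer optimization is included, so
a doubling bracket plus bisection is exact to the requested tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    SatisficingTarget,
    ScaledProblem,
    expected_q,
    feasible_n_max,
    prob_target,
)

__all__ = [
    "EffortTarget",
    "best_expected_detection",
    "best_assurance",
    "performance_curve",
    "min_budget_expected",
    "min_budget_satisficing",
]


@dataclass(frozen=True)
class EffortTarget:
    """Required performance levels for minimum-effort protocols."""

    p_target: Optional[float] = None  # required expected detection probability
    Q_c: Optional[float] = None       # acceptable failed-detection probability
    P_c: Optional[float] = None       # required assurance Pr(Q < Q_c)

    def __post_init__(self) -> None:
        for name in ("p_target", "Q_c", "P_c"):
            val = getattr(self, name)
            if val is not None and not 0.0 < val < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {val}")


def _best_over_n(Bp: float, cp: float, theta: float, score) -> tuple[int, float]:
    sp = ScaledProblem(Bp=Bp, cp=cp, theta=theta)
    n_hi = feasible_n_max(Bp, cp, cap=2048)
    best_n, best_val = 1, -math.inf
    for n in range(1, n_hi + 1):
        val = score(n, sp)
        if val > best_val:
            best_n, best_val = n, val
    return best_n, best_val


def best_expected_detection(Bp: float, cp: float, theta: float) -> tuple[int, float]:
    """(argmax n, value) of the expected detection probability 1 - E[Q]."""
    return _best_over_n(Bp, cp, theta, lambda n, sp: 1.0 - expected_q(n, sp))


def best_assurance(
    Bp: float, cp: float, theta: float, target: SatisficingTarget
) -> tuple[int, float]:
    """(argmax n, value) of the assurance Pr(Q < Q_c)."""
    return _best_over_n(Bp, cp, theta, lambda n, sp: prob_target(n, sp, target))


def performance_curve(
    cp: float,
    theta: float,
    budgets: Sequence[float],
    target: Optional[SatisficingTarget] = None,
) -> pd.DataFrame:
    """Best achievable performance at each budget on a grid.

    Returns one row per budget with the optimized expected detection
    probability (and its n) and, if a target is given, the optimized
    assurance (and its n).  Budgets at or below c' are flagged infeasible.
    """
    budgets = np.asarray(list(budgets), dtype=float)
    if budgets.size == 0 or np.any(budgets <= 0) or np.any(np.diff(budgets) <= 0):
        raise ValueError("budgets must be a strictly positive, increasing grid")
    rows = []
    for Bp in budgets:
        row = {"Bp": Bp, "feasible": Bp > cp,
               "best_n_obj1": np.nan, "expected_detection": np.nan,
               "best_n_obj2": np.nan, "assurance": np.nan}
        if Bp > cp:
            n1, v1 = best_expected_detection(Bp, cp, theta)
            row["best_n_obj1"], row["expected_detection"] = n1, v1
            if target is not None:
                n2, v2 = best_assurance(Bp, cp, theta, target)
                row["best_n_obj2"], row["assurance"] = n2, v2
        rows.append(row)
    return pd.DataFrame(rows)


def _min_budget(requirement, cp: float, tol: float = 1e-6) -> float:
    """Smallest Bp with requirement(Bp) True; requirement monotone in Bp."""
    lo = cp + 1e-6
    hi = max(2.0 * lo, 1.0)
    while not requirement(hi):
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - requirement must eventually hold
            raise RuntimeError("budget bracket exceeded 1e9 scaled units")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if requirement(mid):
            hi = mid
        else:
            lo = mid
    return hi


def min_budget_expected(
    p_target: float, cp: float, theta: float, tol: float = 1e-6
) -> float:
    """Smallest scaled budget achieving max_n (1 - E[Q]) >= p_target."""
    if not 0.0 < p_target < 1.0:
        raise ValueError(f"p_target must lie in (0, 1), got {p_target}")
    if theta == 0:
        # deterministic rate: one visit, pay one fixed cost
        return -math.log(1.0 - p_target) + cp
    return _min_budget(
        lambda Bp: best_expected_detection(Bp, cp, theta)[1] >= p_target, cp, tol
    )


def min_budget_satisficing(
    target: SatisficingTarget, P_c: float, cp: float, theta: float,
    tol: float = 1e-6,
) -> float:
    """Smallest scaled budget achieving max_n Pr(Q < Q_c) >= P_c."""
    if not 0.0 < P_c < 1.0:
        raise ValueError(f"P_c must lie in (0, 1), got {P_c}")
    if theta == 0:
        # assurance jumps 0 -> 1 as soon as B' - c' > -ln Q_c
        return -math.log(target.Q_c) + cp
    return _min_budget(
        lambda Bp: best_assurance(Bp, cp, theta, target)[1] >= P_c, cp, tol
    )
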