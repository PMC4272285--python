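"""Model-free empirical checks of the optimal-survey-number predictions.

Given observed times to first detection from a pool of observer-by-quadrat
search combinations, the probability of failing to detect the species in a
single quadrat searched for time ``t`` is estimated as ``y/v`` — the
fraction of combinations with no detection by ``t`` — and for ``n``
quadrats as ``(y/v)^n`` with ``t = B/n - c``.  A resampling counterpart
tests the satisficing objective: sample ``n`` empirical rates with
replacement and count how often the implied expected number of detections
reaches ``-ln(Q_c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import InfeasibleDesignError, SatisficingTarget, survey_time

__all__ = [
    "empirical_failure_prob",
    "empirical_grid",
    "empirical_optimal_n",
    "satisficing_resample",
    "empirical_optimal_n_satisficing",
    "comparison_stats",
]


def _as_times(times, censored) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("no detection times supplied")
    if censored is None:
        c = np.zeros(t.shape, dtype=bool)
    else:
        c = np.asarray(censored, dtype=bool)
        if c.shape != t.shape:
            raise ValueError("censored mask must match times in shape")
    if np.any(t[~c] <= 0):
        raise ValueError("uncensored detection times must be > 0")
    return t, c


def empirical_failure_prob(
    times: Sequence[float],
    n: int,
    B: float,
    c: float,
    censored: Optional[Sequence[bool]] = None,
) -> float:
    """(y/v)^n: empirical probability of failing in all n quadrats.

    y counts the observer-by-quadrat combinations with no detection by
    t = B/n - c (detection time exceeding t, or censored); v is the total
    number of combinations.
    """
    t_search = survey_time(n, B, c)
    times_arr, cens = _as_times(times, censored)
    failed = cens | (times_arr > t_search)
    return float((failed.sum() / times_arr.size) ** n)


def empirical_grid(
    times: Sequence[float],
    B: float,
    c: float,
    censored: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Full (y/v)^n table over all feasible n."""
    times_arr, cens = _as_times(times, censored)
    rows = []
    n = 1
    while B / n - c > 0:
        t_search = B / n - c
        y = int((cens | (times_arr > t_search)).sum())
        v = int(times_arr.size)
        rows.append({
            "n": n, "t": t_search, "y": y, "v_total": v,
            "failure_prob": (y / v) ** n,
        })
        n += 1
    if not rows:
        raise InfeasibleDesignError(f"no feasible n for B={B}, c={c}")
    return pd.DataFrame(rows)


def empirical_optimal_n(
    times: Sequence[float],
    B: float,
    c: float,
    censored: Optional[Sequence[bool]] = None,
) -> Tuple[int, pd.DataFrame]:
    """argmin over n of (y/v)^n (ties toward smaller n), plus the grid."""
    grid = empirical_grid(times, B, c, censored)
    best = grid.loc[grid["failure_prob"].idxmin()]  # idxmin takes first = smallest n
    return int(best["n"]), grid


def satisficing_resample(
    rates: Sequence[float],
    n: int,
    B: float,
    c: float,
    target: SatisficingTarget,
    reps: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Proportion of resampled n-quadrat searches meeting the detection target.

    Each replicate samples n empirical rates with replacement; success means
    the expected number of detections (B/n - c) * sum(rates) reaches
    -ln(Q_c).
    """
    rates_arr = np.asarray(rates, dtype=float)
    if rates_arr.size == 0:
        raise ValueError("no empirical rates supplied")
    if np.any(rates_arr < 0):
        raise ValueError("rates must be >= 0")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    t_search = survey_time(n, B, c)
    needed = -math.log(target.Q_c)
    rng = np.random.default_rng(seed)
    # sum of n iid draws per replicate, chunked to bound memory
    hits = 0
    done = 0
    chunk = max(1, min(reps, 4_000_000 // max(n, 1)))
    while done < reps:
        k = min(chunk, reps - done)
        sums = rates_arr[rng.integers(0, rates_arr.size, size=(k, n))].sum(axis=1)
        hits += int(np.sum(t_search * sums >= needed))
        done += k
    return hits / reps


def empirical_optimal_n_satisficing(
    rates: Sequence[float],
    B: float,
    c: float,
    target: SatisficingTarget,
    reps: int = 1_000_000,
    seed: int = 0,
) -> Tuple[int, pd.DataFrame]:
    """argmax over n of the resampled success proportion (ties toward smaller n).

    Each n uses a seed derived deterministically from the master seed so runs
    are comparable and reproducible.
    """
    master = np.random.SeedSequence(seed)
    rows = []
    n = 1
    while B / n - c > 0:
        child = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
        prop = satisficing_resample(rates, n, B, c, target, reps=reps, seed=child)
        rows.append({"n": n, "t": B / n - c, "success_prop": prop})
        n += 1
    if not rows:
        raise InfeasibleDesignError(f"no feasible n for B={B}, c={c}")
    grid = pd.DataFrame(rows)
    best = grid.loc[grid["success_prop"].idxmax()]
    return int(best["n"]), grid


def comparison_stats(
    predicted: Sequence[float], observed: Sequence[float]
) -> dict:
    """Least-squares slope (with s.e.) and Pearson r of predicted vs observed."""
    x = np.asarray(predicted, dtype=float)
    yv = np.asarray(observed, dtype=float)
    if x.size != yv.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    res = stats.linregress(x, yv)
    return {
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "intercept": float(res.intercept),
        "pearson_r": float(res.rvalue),
    }
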