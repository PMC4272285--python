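"""Synthetic field-data generator with known ground truth.

Emulates the two record shapes the estimators consume: timed quadrat
searches (observer-by-quadrat grid, exponential time to first detection,
censored at the session end) and repeat-survey counts (sites visited
several times, Poisson counts with a log-linear abundance effect and
optionally correlated visit-level rates).  Ground-truth parameters live in
the spec, so every estimator can be exercised by parameter recovery without
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .core import RatePrior
from .estimate import DetectionRecord, SurveyCountRecord
from .simulate import CorrelationSpec, draw_rates

__all__ = [
    "ScenarioSpec",
    "gen_quadrat_experiment",
    "gen_repeat_surveys",
    "load_preset",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth description of a simulated survey campaign.

    `rate` is the detection-rate distribution at abundance 1;
    `abundance_exponent` scales the mean as abundance**exponent for the
    repeat-survey shape.  The observer/quadrat layout drives the timed
    search shape; the site/visit layout drives the count shape.
    """

    rate: RatePrior
    seed: int = 0
    corr: CorrelationSpec = field(default_factory=CorrelationSpec)
    n_observers: int = 14
    n_quadrats: int = 9
    session_length: float = 15.0
    n_sites: int = 29
    visits_min: int = 2
    visits_max: int = 9
    search_time: float = 1.0
    abundances: Optional[Sequence[float]] = None
    abundance_exponent: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_observers, self.n_quadrats, self.n_sites) < 1:
            raise ValueError("layout dimensions must be positive")
        if self.session_length <= 0 or self.search_time <= 0:
            raise ValueError("session_length and search_time must be > 0")
        if not 1 <= self.visits_min <= self.visits_max:
            raise ValueError("need 1 <= visits_min <= visits_max")


def gen_quadrat_experiment(spec: ScenarioSpec) -> List[DetectionRecord]:
    """Timed quadrat searches: one record per observer-by-quadrat pair.

    The pair's rate is a lognormal draw with the spec's (mu, sigma); the
    time to first detection is exponential given the rate and censored at
    the session length.  Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_units = spec.n_observers * spec.n_quadrats
    if spec.rate.sigma == 0:
        lam = np.full(n_units, spec.rate.mu)
    else:
        lam = draw_rates(1, spec.rate, None, n_units, rng)[:, 0]
    ttd = rng.exponential(1.0 / np.maximum(lam, 1e-300))
    records = []
    k = 0
    for o in range(spec.n_observers):
        for q in range(spec.n_quadrats):
            cens = bool(ttd[k] > spec.session_length)
            records.append(DetectionRecord(
                observer=f"obs{o + 1:02d}",
                quadrat=f"quad{q + 1:02d}",
                time_to_first_detection=(
                    spec.session_length if cens else float(ttd[k])
                ),
                session_length=spec.session_length,
                censored=cens,
            ))
            k += 1
    return records


def gen_repeat_surveys(spec: ScenarioSpec) -> List[SurveyCountRecord]:
    """Repeat-survey counts: sites visited 2-9 times, Poisson detections.

    The log rate is ln(mu at abundance 1) + exponent*ln(abundance) plus a
    visit-level lognormal deviate, correlated across visits within a site
    per the spec's correlation structure.  Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    abund = (np.asarray(spec.abundances, dtype=float)
             if spec.abundances is not None
             else rng.choice([1.0, 2.0, 3.0], size=spec.n_sites))
    if abund.size != spec.n_sites:
        raise ValueError("abundances must have one entry per site")
    records: List[SurveyCountRecord] = []
    for i in range(spec.n_sites):
        n_visits = int(rng.integers(spec.visits_min, spec.visits_max + 1))
        scale = abund[i] ** spec.abundance_exponent
        site_rate = RatePrior(mu=spec.rate.mu * scale,
                              sigma=spec.rate.sigma * scale)
        if site_rate.sigma == 0:
            lam = np.full(n_visits, site_rate.mu)
        else:
            lam = draw_rates(n_visits, site_rate, spec.corr, 1, rng)[0]
        counts = rng.poisson(lam * spec.search_time)
        for v in range(n_visits):
            records.append(SurveyCountRecord(
                site=f"site{i + 1:03d}", visit=v + 1,
                detections=int(counts[v]),
                search_time=spec.search_time,
                abundance=float(abund[i]),
            ))
    return records


def load_preset(name: str) -> dict:
    """Load a shipped scenario preset ('frog' or 'plants') as a dict."""
    ref = resources.files("surveydesign.presets").joinpath(f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"unknown preset {name!r}") from exc
    return yaml.safe_load(text)
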