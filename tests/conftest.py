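import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from surveydesign import (
    DesignProblem,
    RatePrior,
    SatisficingTarget,
    ScaledProblem,
    scale_problem,
)


@pytest.fixture
def frog_low() -> ScaledProblem:
    """Stream-frog problem at low abundance: mu=0.67/h, theta=2.5, B=10h, c=1h."""
    return scale_problem(
        DesignProblem(B=10.0, c=1.0, rate=RatePrior.from_cv(0.67, 2.5))
    )


@pytest.fixture
def frog_high() -> ScaledProblem:
    """Same survey season at high abundance: mu=2.2/h."""
    return scale_problem(
        DesignProblem(B=10.0, c=1.0, rate=RatePrior.from_cv(2.2, 2.5))
    )


@pytest.fixture
def lomandra() -> ScaledProblem:
    """Timed plant-search problem: mu=0.56/min, sigma=0.64/min, B=15, c=0.25."""
    return scale_problem(
        DesignProblem(B=15.0, c=0.25, rate=RatePrior(mu=0.56, sigma=0.64))
    )


@pytest.fixture
def atriplex() -> ScaledProblem:
    return scale_problem(
        DesignProblem(B=15.0, c=0.25, rate=RatePrior(mu=0.55, sigma=0.60))
    )


@pytest.fixture
def qc05() -> SatisficingTarget:
    return SatisficingTarget(Q_c=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140)
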