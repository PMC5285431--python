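"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lemsurv as lv

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Root seed for every stochastic fixture in the suite.
SUITE_SEED = 20170131


@pytest.fixture(scope="session")
def models():
    """Benchmark interpolation models, one per spectrum."""
    return lv.benchmark_models()


@pytest.fixture(scope="session")
def model_100kvp(models):
    return models["100 kVp"]


@pytest.fixture(scope="session")
def fixture_dataset():
    """Standard synthetic benchmark-layout dataset (12 curves) plus truth."""
    return lv.generate_benchmark_fixture(seed=SUITE_SEED)


def noiseless_curve(params: lv.LQParameters, doses) -> lv.SurvivalCurve:
    """Exact LQ curve sampled at the given doses (the fit round-trip input)."""
    measurements = tuple(
        lv.SurvivalMeasurement(
            dose=float(d),
            sf_mean=float(np.exp(-(params.alpha * d + params.beta * d * d))),
        )
        for d in doses
    )
    return lv.SurvivalCurve(
        spectrum_label=params.spectrum_label,
        concentration=params.concentration,
        measurements=measurements,
    )


def lq_grid_objective_min(
    doses, y, *, step=1e-4, bound=0.5, chunk=256
) -> float:
    """Exhaustive grid-search oracle for the log-space NNLS objective.

    Minimises sum_i (y_i - a*d_i - b*d_i^2)^2 over the grid
    a, b in {0, step, ..., bound}, using the expanded quadratic form so each
    grid point costs O(1) after precomputing the data sums.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(y, dtype=float)
    s2, s3, s4 = np.sum(doses**2), np.sum(doses**3), np.sum(doses**4)
    sdy, sd2y = np.sum(doses * y), np.sum(doses**2 * y)
    const = float(np.sum(y**2))
    grid = np.arange(0.0, bound + step / 2.0, step)
    b_part = grid**2 * s4 - 2.0 * grid * sd2y  # beta-only terms
    best = np.inf
    for i in range(0, grid.size, chunk):
        a = grid[i : i + chunk, None]
        obj = (a**2 * s2 - 2.0 * a * sdy) + b_part[None, :] + 2.0 * s3 * a * grid[None, :]
        best = min(best, float(obj.min()))
    return const + best
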