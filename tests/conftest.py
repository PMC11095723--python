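"""Shared fixtures.

The expensive artefacts (noiseless dataset, the 100-start recovery fit)
are session-scoped and reused by the calibration, identifiability and
acceptance tests.
"""

from __future__ import annotations

import pandas as pd
import pytest

from cellgrowth import (
    ParameterSet,
    default_synthetic_constants,
    default_synthetic_parameters,
    model_by_name,
)
from cellgrowth.calibration import multistart_fit, physical_search_space
from cellgrowth.synthetic import (
    ExperimentalDesign,
    NoiseSpec,
    TimeSeriesDataset,
    generate_dataset,
)

#: reduced-budget stage options used by desk-scale fits in the suite
FAST_STAGE_OPTIONS = {
    "stage1_iters": 20,
    "stage1_step": 0.1,
    "n_refine": 8,
    "refine_maxiter": 60,
    "polish_n": 4,
    "polish_maxfev": 250,
}


def selection_fixture_params() -> ParameterSet:
    """Published modulating constants (nearly flat over the experimental
    ranges) with the per-well-unit consumption rate of the synthetic
    fixture; used where the published-like regime matters."""
    return ParameterSet(
        beta=3.83e-5, delta=3.12e-5, V_g=2.0e-12, cbar_g=1.66,
        K_o=1.88e-5, K_g=6.86e-7, K_l=8602.0,
    )


@pytest.fixture(scope="session")
def fixture_model():
    return model_by_name("OxyGluLac")


@pytest.fixture(scope="session")
def fixture_params():
    return default_synthetic_parameters()


@pytest.fixture(scope="session")
def fixture_consts():
    return default_synthetic_constants()


@pytest.fixture(scope="session")
def small_design():
    """Two environments x two seedings, 3 replicates, 24 h schedule."""
    return ExperimentalDesign(
        environments=((25.0, 0.18), (5.5, 0.05)),
        seedings=(50_000.0, 200_000.0),
        replicates=3,
        sampling_period_h=24.0,
    )


@pytest.fixture(scope="session")
def cond_map(small_design):
    return dict(small_design.conditions())


@pytest.fixture(scope="session")
def noiseless_dataset(fixture_model, fixture_params, fixture_consts, small_design):
    return generate_dataset(
        fixture_model, fixture_params, fixture_consts, small_design,
        NoiseSpec(epsilon=0.0, seed=1),
    )


@pytest.fixture(scope="session")
def recovery_fit(fixture_model, fixture_consts, noiseless_dataset, cond_map):
    """100-start calibration of the generating model on noiseless data."""
    return multistart_fit(
        fixture_model, fixture_consts, noiseless_dataset, cond_map,
        space=physical_search_space(fixture_model),
        n_starts=100, seed=3, stage_options=dict(FAST_STAGE_OPTIONS),
    )


def manual_dataset(cells: list[tuple[str, float, str, list[float]]]) -> TimeSeriesDataset:
    """Dataset from explicit (condition, time, observable, replicates)."""
    rows = []
    for cid, t, obs, values in cells:
        for rep, v in enumerate(values):
            rows.append((cid, rep, float(t), obs, float(v)))
    return TimeSeriesDataset(pd.DataFrame(
        rows, columns=["condition_id", "replicate", "time_h", "observable", "value"]
    ))
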