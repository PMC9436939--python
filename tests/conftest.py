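import numpy as np
import pandas as pd
import pytest

from mvgee import (
    CovariateSpec,
    ModelSpec,
    PanelDataset,
    SimulationConfig,
    generate_panel,
    recovery_config,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """8-subject study-regime panel; small enough for oracle comparisons."""
    return recovery_config(n_subjects=8, seed=3)


@pytest.fixture(scope="session")
def tiny_panel(tiny_config) -> PanelDataset:
    return generate_panel(tiny_config)


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    return ModelSpec(
        responses=("FBS", "HbA1c"),
        covariates=("family_history_diabetes", "systolic_bp"),
        interaction_set=frozenset({"intercept", "time", "family_history_diabetes"}),
    )


@pytest.fixture
def simple_config() -> SimulationConfig:
    """Two covariates, moderate effects, exchangeable 0.4 — fast to simulate."""
    return SimulationConfig(
        n_subjects=60,
        visit_times=(0.0, 3.0, 6.0, 9.0),
        covariates=(
            CovariateSpec("x_bin", "binary", prevalence=0.5),
            CovariateSpec("x_cont", "continuous", mean=0.0, sd=1.0),
        ),
        true_beta={
            "A": {"intercept": 10.0, "time": -0.5, "x_bin": 2.0, "x_cont": 1.0},
            "B": {"intercept": 1.0, "time": -0.1, "x_bin": 2.0, "x_cont": -0.5},
        },
        residual_sd={"A": 2.0, "B": 1.0},
        within_corr=0.4,
        seed=11,
    )


def two_by_two_panel() -> PanelDataset:
    """Hand-written 2 subjects x 2 visits x 2 responses panel."""
    rows = []
    values = iter(range(8))
    for sid in ("S1", "S2"):
        for t in (0.0, 3.0):
            for resp in ("A", "B"):
                rows.append(
                    {
                        "subject_id": sid,
                        "visit_time": t,
                        "response": resp,
                        "value": float(next(values)),
                        "x1": 1.0 if sid == "S1" else 0.0,
                    }
                )
    return PanelDataset(pd.DataFrame(rows))


@pytest.fixture
def small_panel() -> PanelDataset:
    return two_by_two_panel()
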