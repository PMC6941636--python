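import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import jointfrailty as jf

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grade_schema() -> jf.CovariateSchema:
    return jf.CovariateSchema(
        covariates=(jf.Covariate("grade", ("I", "II", "III"), "I"),),
        design_1=("grade",), design_2=("grade",))


@pytest.fixture(scope="session")
def toy_config(grade_schema) -> jf.SimulationConfig:
    """Small cohort with realistic (sparse) event counts and strong frailty."""
    return jf.SimulationConfig(
        n_subjects=8, schema=grade_schema,
        covariate_model={"grade": jf.CategoricalModel(("I", "II", "III"),
                                                      (0.3, 0.4, 0.3))},
        baseline_1=jf.WeibullHazard(1.0, 800.0),
        baseline_2=jf.WeibullHazard(1.0, 2000.0),
        frailty=jf.FrailtyCovariance(1.10, 7.39, 0.5),
        beta_1={"grade": {"II": 0.5, "III": 1.0}},
        beta_2={"grade": {"II": 0.3, "III": 0.8}},
        horizon=150.0, seed=7)


@pytest.fixture(scope="session")
def toy_history(toy_config):
    history, _ = jf.simulate_cohort(toy_config)
    return history


@pytest.fixture(scope="session")
def toy_params(toy_config) -> jf.JointFrailtyParams:
    """True generating parameters of the toy cohort, as a likelihood point."""
    return jf.JointFrailtyParams(
        baselines={"1": toy_config.baseline_1, "2": toy_config.baseline_2},
        betas={"1": np.array([0.5, 1.0]), "2": np.array([0.3, 0.8])},
        frailty=toy_config.frailty)


@pytest.fixture(scope="session")
def medium_config(grade_schema) -> jf.SimulationConfig:
    """Information-rich cohort (many events) for fitting tests."""
    return jf.SimulationConfig(
        n_subjects=250, schema=grade_schema,
        covariate_model={"grade": jf.CategoricalModel(("I", "II", "III"),
                                                      (0.3, 0.4, 0.3))},
        baseline_1=jf.WeibullHazard(1.0, 60.0),
        baseline_2=jf.WeibullHazard(1.0, 90.0),
        frailty=jf.FrailtyCovariance(0.8, 1.5, 0.4),
        beta_1={"grade": {"II": 0.5, "III": 1.0}},
        beta_2={"grade": {"II": 0.3, "III": 0.8}},
        horizon=60.0, max_recurrences_per_type=200, seed=11)


@pytest.fixture(scope="session")
def medium_history(medium_config):
    history, _ = jf.simulate_cohort(medium_config)
    return history


def make_history(events_rows, covariate_rows, schema) -> jf.EventHistory:
    events = pd.DataFrame(events_rows,
                          columns=["subject_id", "event_type", "start",
                                   "stop", "status"])
    covariates = pd.DataFrame(covariate_rows)
    return jf.EventHistory(events=events, covariates=covariates, schema=schema)
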