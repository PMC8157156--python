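"""Shared fixtures: small synthetic processes with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from crashsev.datasets import (
    CovariateSpec,
    RandomCoefficient,
    SyntheticConfig,
    TrueParameterSet,
    YearConfig,
    generate_dataset,
)
from crashsev.mixedlogit import ModelSpec


@pytest.fixture(scope="session")
def simple_covariates():
    return (
        CovariateSpec("restraint", "occupant", 0.7),
        CovariateSpec("male", "driver", 0.6),
        CovariateSpec("wet", "roadway", 0.3),
    )


@pytest.fixture(scope="session")
def mnl_truth(simple_covariates):
    """A purely fixed-coefficient generating process."""
    return TrueParameterSet(
        constants={"I": -0.7, "FI": -4.0},
        fixed_coefficients={("I", "restraint"): -0.8, ("FI", "male"): 0.6},
    )


@pytest.fixture(scope="session")
def mixed_truth(simple_covariates):
    """One random coefficient in the strongly identified regime (sd > |mean|)."""
    return TrueParameterSet(
        constants={"I": -0.4, "FI": -4.0},
        fixed_coefficients={("I", "wet"): 0.5, ("FI", "male"): 0.8},
        random_coefficients=(
            RandomCoefficient("I", "restraint", mean=-1.5, sd=3.0),
        ),
    )


@pytest.fixture(scope="session")
def mnl_data(simple_covariates, mnl_truth):
    cfg = SyntheticConfig(
        n_crashes=2000, covariates=simple_covariates, truth=mnl_truth, seed=42
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def mnl_spec(mnl_truth):
    return ModelSpec.from_truth(mnl_truth)


@pytest.fixture(scope="session")
def two_year_config(simple_covariates, mnl_truth):
    return SyntheticConfig(
        n_crashes=1000,
        covariates=simple_covariates,
        truth=mnl_truth,
        years=(YearConfig(2017), YearConfig(2018)),
        seed=7,
    )
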