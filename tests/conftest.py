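"""Shared fixtures: small simulated clustered cohorts built from known truth."""

import logging

import numpy as np
import pandas as pd
import pytest

from bridgejoint.design import ModelSpec, build_design
from bridgejoint.params import ParameterVector
from bridgejoint.simulate import generate_outcomes

logging.getLogger("bridgejoint").setLevel(logging.WARNING)


def binary_spec() -> ModelSpec:
    """Joint spec with one shared numeric binary predictor ``x``."""
    return ModelSpec(predictors1=["x"], predictors2=["x"])


def simulate_joint(seed: int, n_clusters: int = 10, cluster_size: int = 50,
                   truth: ParameterVector | None = None,
                   spec: ModelSpec | None = None):
    """Cohort table with one binary predictor drawn from known truth."""
    spec = spec or binary_spec()
    truth = truth or ParameterVector(
        [-2.0, -2.5], [[np.log(4)], [0.0]], [-2.0, -2.5], [[0.5], [0.3]],
        0.6, 0.6, 0.5, names1=["x"], names2=["x"])
    rng = np.random.default_rng(seed)
    n = n_clusters * cluster_size
    cov = pd.DataFrame({"hospital": np.repeat(np.arange(n_clusters), cluster_size),
                        "x": rng.integers(0, 2, n)})
    df = generate_outcomes(cov, truth, spec, seed=seed + 10_000)
    return df, truth, spec


@pytest.fixture(scope="session")
def small_cohort():
    """10 clusters x 50 with a strong preterm effect; used across modules."""
    df, truth, spec = simulate_joint(3)
    return df, truth, spec


@pytest.fixture(scope="session")
def small_design(small_cohort):
    df, truth, spec = small_cohort
    return build_design(df, spec), truth
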