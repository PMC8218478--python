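import dataclasses

import numpy as np
import pytest

from lcra import (
    FitConfig,
    LCRAParameters,
    default_codebook,
    default_study_spec,
    encode,
    fit_em,
    generate_cohort,
)
from lcra.codebook import EncodedDesign


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def study_spec():
    return default_study_spec()


@pytest.fixture(scope="session")
def separated_spec():
    """Well-separated generating parameters for recovery experiments."""
    return default_study_spec(separation=2.0)


@pytest.fixture(scope="session")
def small_cohort(study_spec, codebook):
    """A 250-case synthetic cohort with outcomes and true labels."""
    records, labels = generate_cohort(
        dataclasses.replace(study_spec, n=250, seed=2024), codebook
    )
    return records, labels


@pytest.fixture(scope="session")
def small_design(small_cohort, codebook):
    records, _ = small_cohort
    return encode(records, codebook)


@pytest.fixture(scope="session")
def two_class_params():
    """Closed-form two-class parameters: memberships (0.5, 0.5) for any
    covariates; class outcome profiles (0.7, 0.2, 0.1) and (0.1, 0.2, 0.7)."""
    gamma = np.zeros((1, 18))
    beta = np.zeros((2, 2, 9))
    beta[0, 0, 0] = np.log(0.2 / 0.7)
    beta[0, 1, 0] = np.log(0.1 / 0.7)
    beta[1, 0, 0] = np.log(0.2 / 0.1)
    beta[1, 1, 0] = np.log(0.7 / 0.1)
    return LCRAParameters(gamma=gamma, beta=beta)


@pytest.fixture(scope="session")
def tiny_design():
    """A deterministic 3-covariate / 2-predictor design used where the
    full 17/8 study layout is irrelevant."""
    rng = np.random.default_rng(7)
    n = 120
    return EncodedDesign(
        covariate_matrix=rng.normal(size=(n, 3)),
        predictor_matrix=rng.normal(size=(n, 2)),
        outcome_vector=rng.integers(0, 3, size=n),
        covariate_names=["c1", "c2", "c3"],
        predictor_names=["p1", "p2"],
        reference_levels={},
    )


@pytest.fixture(scope="session")
def fitted_small(small_design):
    """A seeded 2-class fit on the small cohort, shared across tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_em(
            small_design,
            FitConfig(n_classes=2, n_restarts=3, max_iter=300, tol=1e-7, seed=42),
        )


def random_params(rng, K=3, Q=17, P=8, scale=0.5):
    """Random valid parameters for property tests."""
    gamma = rng.normal(scale=scale, size=(K - 1, 1 + Q)) if K > 1 else np.zeros((0, 1 + Q))
    beta = rng.normal(scale=scale, size=(K, 2, 1 + P))
    return LCRAParameters(gamma=gamma, beta=beta)
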