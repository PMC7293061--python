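import numpy as np
import pandas as pd
import pytest

import stressecho as se


@pytest.fixture(scope="session")
def full_spec():
    return se.default_cohort_spec("full")


@pytest.fixture(scope="session")
def nocad_spec():
    return se.default_cohort_spec("no_prior_cad")


@pytest.fixture(scope="session")
def study_cohort(full_spec):
    """A study-sized synthetic cohort (82 positive / 447 negative)."""
    return se.generate_cohort(full_spec, 82, 447, seed=7)


@pytest.fixture(scope="session")
def planted():
    """Small planted cohort: 2 informative, 3 noise features, strong effect."""
    cohort, truth = se.generate_planted_cohort(300, 2, 3, 0.6, seed=11)
    return cohort, truth


def random_encoded_matrix(rng, n_rows=None, n_features=None, n_levels=3):
    """Random discrete matrix with both labels present (test helper)."""
    n = n_rows or int(rng.integers(10, 41))
    f = n_features or int(rng.integers(3, 7))
    X = pd.DataFrame(
        rng.integers(0, n_levels, size=(n, f)),
        columns=[f"f{j}" for j in range(f)],
    )
    y = np.where(rng.integers(0, 2, size=n) == 1, "positive", "negative").astype(object)
    y[0], y[1] = "positive", "negative"
    return se.EncodedMatrix(X, y)
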