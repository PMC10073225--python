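import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from braingut.cohort import CohortSpec, CovariateModel, generate_cohort
from braingut.connectome import WeightedNetwork
from braingut.features import FeatureMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """An 18-subject, 12-region, 15-metabolite cohort with planted signal."""
    spec = CohortSpec(
        n_obese=10, n_overweight=8, n_regions=12, n_metabolites=15,
        informative_brain_regions=[0, 1], informative_metabolites=[0, 1, 2],
        brain_effect=1.8, metabolite_effect=1.5, seed=42, edge_density=0.7,
    )
    return generate_cohort(spec)


def make_network(W: np.ndarray) -> WeightedNetwork:
    n = W.shape[0]
    return WeightedNetwork(weights=W, region_names=[f"r{i}" for i in range(n)])


def planted_features(
    n: int = 60,
    n_informative: int = 2,
    n_noise: int = 8,
    effect: float = 3.0,
    seed: int = 0,
    balance: tuple[int, int] | None = None,
) -> FeatureMatrix:
    """A feature matrix whose first columns separate the groups by ``effect`` SDs."""
    rng = np.random.default_rng(seed)
    if balance is None:
        n0 = n // 2
    else:
        n0 = balance[0]
        n = sum(balance)
    y = np.array([0] * n0 + [1] * (n - n0))
    y = y[rng.permutation(n)]
    p = n_informative + n_noise
    X = rng.normal(size=(n, p))
    X[:, :n_informative] += effect * y[:, None]
    names = [f"inf{i}" for i in range(n_informative)] + [f"noise{i}" for i in range(n_noise)]
    covariates = pd.DataFrame(
        {
            "age": rng.normal(32, 10, n),
            "sex": rng.integers(0, 2, n),
            "diet": rng.integers(0, 2, n),
        }
    )
    return FeatureMatrix(pd.DataFrame(X, columns=names), pd.Series(y), covariates)
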