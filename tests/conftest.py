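import warnings

import numpy as np
import pandas as pd
import pytest

from esdm import GridSpec, default_niche, generate_env_stack, generate_virtual_species
from esdm.sdm_core import TrainingTable, balanced_weights

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")

#: fast hyperparameter overrides used by unit tests (the algorithms' behavior,
#: not their defaults, is what these tests probe)
LIGHT_HYPERPARAMETERS = {
    "GBM": {"n_estimators": 150, "learning_rate": 0.1},
    "RF": {"n_estimators": 100},
    "ANN": {"max_iter": 300},
    "SRE": {"quantile": 0.0},  # min/max envelope: no presence is trimmed
}


@pytest.fixture(scope="session")
def small_grid():
    # 20×20 cells over a 20°×20° window of the study area
    return GridSpec(lon_min=100, lon_max=120, lat_min=-10, lat_max=10, cell_size=1.0)


@pytest.fixture(scope="session")
def small_stack(small_grid):
    return generate_env_stack(small_grid, smoothness=2.0, seed=11)


@pytest.fixture(scope="session")
def small_species(small_stack):
    presences, truth = generate_virtual_species(
        small_stack, default_niche(n_presences=40), seed=12
    )
    return presences, truth


def make_separable_table(n_per_class=60, seed=0):
    """Linearly separable toy table: class 1 at x1≈+2, class 0 at x1≈−2."""
    rng = np.random.default_rng(seed)
    x1 = np.concatenate([rng.normal(2, 0.3, n_per_class), rng.normal(-2, 0.3, n_per_class)])
    x2 = rng.normal(0, 1, 2 * n_per_class)
    y = np.repeat([1, 0], n_per_class)
    data = pd.DataFrame({"a": x1, "b": x2, "response": y})
    data["weight"] = balanced_weights(y)
    return TrainingTable(data=data, predictors=["a", "b"])


@pytest.fixture()
def separable_table():
    return make_separable_table()
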