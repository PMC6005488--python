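import numpy as np
import pytest

import costfs as cf


@pytest.fixture(scope="session")
def liver():
    """The packaged 6-instance liver-panel subtable with its cost vector."""
    return cf.fixture_liver_subtable()


@pytest.fixture(scope="session")
def liver_system(liver):
    return liver[0]


@pytest.fixture(scope="session")
def liver_costs(liver):
    return liver[1]


@pytest.fixture(scope="session")
def liver_importance():
    return cf.fixture_liver_importance()


@pytest.fixture(scope="session")
def liver_nbr_cfg(liver_system):
    return cf.NeighborhoodConfig.for_system(liver_system)


def random_system(rng: np.random.Generator, n_instances: int = 12,
                  n_features: int = 6, n_classes: int = 2) -> cf.DecisionSystem:
    """A small fully random normalized system for enumeration oracles."""
    values = rng.uniform(0.0, 1.0, (n_instances, n_features))
    labels = rng.integers(0, n_classes, n_instances)
    return cf.normalize(cf.DecisionSystem(
        instance_ids=tuple(f"x{i}" for i in range(n_instances)),
        features=tuple(f"f{r}" for r in range(n_features)),
        values=values,
        decisions=tuple(int(v) for v in labels),
    ))
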