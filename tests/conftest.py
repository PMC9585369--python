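"""Shared fixtures: reference-condition synthetic tables and orderings."""

import numpy as np
import pytest

from instarcluster import (
    GeneratorConfig,
    NeighborhoodParams,
    generate_instar_dataset,
    generated_truth,
    optics_order,
)


@pytest.fixture(scope="session")
def default_table():
    """240-specimen table drawn under the reference study conditions."""
    return generate_instar_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_truth(default_table):
    return generated_truth(default_table)


@pytest.fixture(scope="session")
def default_optics(default_table):
    """OPTICS ordering of the default table at minPts = 5, eps = inf."""
    return optics_order(default_table, NeighborhoodParams(np.inf, 5))


@pytest.fixture(scope="session")
def six_points():
    """The 1-D worked example: two triplets 8 apart."""
    return np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0]).reshape(-1, 1)
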