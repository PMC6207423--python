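"""Shared fixtures for the manakin test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon

from manakin.io_formats import RangePolygon, parse_tree_string

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: 4-taxon ultrametric tree used across MCMC tests
FOUR_TAXON_NEWICK = (
    "(manacus:1.0,(vitellinus:0.5,(candei:0.25,aurantiacus:0.25):0.25):0.5);"
)


@pytest.fixture
def four_taxon_tree():
    return parse_tree_string(FOUR_TAXON_NEWICK)


@pytest.fixture
def unit_square():
    return RangePolygon(
        Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]), name="unit_square"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
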