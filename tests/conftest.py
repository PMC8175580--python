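import numpy as np
import pytest

from minslab import Geometry, Totals, default_parameters


@pytest.fixture(scope="session")
def params_totals():
    return default_parameters()


@pytest.fixture(scope="session")
def params(params_totals):
    return params_totals[0]


@pytest.fixture(scope="session")
def totals(params_totals):
    return params_totals[1]


def totals_at(totals, ed):
    return Totals.from_ed_ratio(totals.n_D, ed)


@pytest.fixture
def slab_geom():
    return Geometry(H=4.0, dz=4.0 / 24)
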