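import numpy as np
import pytest

from minibeams.geometry import make_scenario
from minibeams.physics import RangeModel
from minibeams.optics import build_field_table
from minibeams.dose import compute_dose


@pytest.fixture(scope="session")
def rm_tab():
    return RangeModel(mode="tabulated")


@pytest.fixture(scope="session")
def rm_pl():
    return RangeModel(mode="power-law")


@pytest.fixture(scope="session")
def config1():
    return make_scenario("config1")


@pytest.fixture(scope="session")
def config3p():
    return make_scenario("config3p")


@pytest.fixture(scope="session")
def field_table_3p_150(config3p, rm_tab):
    return build_field_table(config3p, [150.0], range_model=rm_tab)


@pytest.fixture(scope="session")
def grid_config1_150(config1, rm_tab):
    return compute_dose(config1, energy=150.0, grid="coarse", range_model=rm_tab)


@pytest.fixture(scope="session")
def grid_config3p_150(config3p, field_table_3p_150, rm_tab):
    return compute_dose(config3p, energy=150.0, field_table=field_table_3p_150,
                        grid="coarse", range_model=rm_tab)
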