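import pytest

from fmea_triz import case_study
from fmea_triz.fuzzy import default_scale
from fmea_triz.triz import load_determinant_map, load_matrix, load_parameters, load_principles


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def register():
    return case_study.failure_register()


@pytest.fixture(scope="session")
def case_means():
    return case_study.fuzzy_means()


@pytest.fixture(scope="session")
def case_panel(scale):
    # reverse-fitted synthetic panel reproducing the printed per-cell means
    return case_study.case_panel(scale)


@pytest.fixture(scope="session")
def matrix():
    return load_matrix()


@pytest.fixture(scope="session")
def dmap():
    return load_determinant_map()


@pytest.fixture(scope="session")
def registries():
    return load_parameters(), load_principles()


@pytest.fixture(scope="session")
def blueprints():
    return case_study.blueprints()
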