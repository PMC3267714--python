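import pytest

from uhccost.aggregate import default_surgical_monthly
from uhccost.costing import load_price_list, load_protocols
from uhccost.params import _data_path, load_parameters


@pytest.fixture(scope="session")
def config():
    """(registry, macro, profiles) from the shipped default fixtures."""
    return load_parameters()


@pytest.fixture(scope="session")
def registry(config):
    return config[0]


@pytest.fixture(scope="session")
def macro(config):
    return config[1]


@pytest.fixture(scope="session")
def profiles(config):
    return config[2]


@pytest.fixture(scope="session")
def protocols():
    return load_protocols(_data_path("protocols.csv"))


@pytest.fixture(scope="session")
def prices():
    return load_price_list(_data_path("price_list.csv"))


@pytest.fixture(scope="session")
def surgical_monthly():
    return default_surgical_monthly()


#: Reference demand/cost table: specialty -> (opd_visits, bed_days,
#: opd_branded, ipd_branded, opd_generic, ipd_generic); surgical specialties
#: carry None costs (pooled into the surgical package line).
REFERENCE_TABLE = {
    "ent": (735, 97, 463360, 107519, 272963, 59386),
    "dental": (554, 2, 346745, 3658, 300278, 3658),
    "dermatology": (1290, 170, 292776, 64107, 168410, 51121),
    "ophthalmology": (727, 78, 951991, 588683, 867041, 568222),
    "psychiatry": (168, 17, 200055, 14338, 141003, 9302),
    "general_medicine": (2400, 343, 4119882, 716528, 2332485, 413427),
    "orthopedics": (974, 488, None, None, None, None),
    "gynecology": (1540, 214, 1132900, 293062, 812763, 221684),
    "pediatrics": (1263, 253, 771727, 164589, 566264, 100540),
    "surgery": (1148, 321, None, None, None, None),
}

SURGICAL_MONTHLY = 1_441_994
TOTAL_BRANDED = 11_673_914
TOTAL_GENERIC = 8_330_541


@pytest.fixture(scope="session")
def reference_table():
    return REFERENCE_TABLE
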