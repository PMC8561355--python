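"""Shared fixtures: the packaged hospital case study and its published results.

The expected tables are frozen from the study's printed intermediate and
final matrices (3 d.p.), keyed (criterion, alternative) -> (l, m, u).
"""

import pytest
from hypothesis import settings

from cytomaint import casestudy

settings.register_profile("seeded", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("seeded")


@pytest.fixture(scope="session")
def hospital_problem():
    return casestudy.reference_problem()


@pytest.fixture(scope="session")
def hospital_systems():
    return casestudy.alternative_systems()


ALTERNATIVES = ("CPM", "CPM+C", "CPM+2C", "CPPM")

#: Normalised fuzzy decision matrix, 3 d.p.
EXPECTED_NORMALISED = {
    ("QH", "CPM"): (0.000, 0.000, 0.100),
    ("QH", "CPM+C"): (0.900, 1.000, 1.000),
    ("QH", "CPM+2C"): (0.900, 1.000, 1.000),
    ("QH", "CPPM"): (0.700, 0.900, 1.000),
    ("MC", "CPM"): (0.900, 1.000, 1.000),
    ("MC", "CPM+C"): (0.500, 0.700, 0.900),
    ("MC", "CPM+2C"): (0.300, 0.600, 0.900),
    ("MC", "CPPM"): (0.000, 0.000, 0.100),
    ("IC", "CPM"): (0.900, 1.000, 1.000),
    ("IC", "CPM+C"): (0.300, 0.600, 0.900),
    ("IC", "CPM+2C"): (0.000, 0.100, 0.300),
    ("IC", "CPPM"): (0.900, 1.000, 1.000),
    ("MP", "CPM"): (0.300, 0.500, 0.700),
    ("MP", "CPM+C"): (0.500, 0.750, 1.000),
    ("MP", "CPM+2C"): (0.500, 0.750, 1.000),
    ("MP", "CPPM"): (0.900, 1.000, 1.000),
    ("IH", "CPM"): (0.100, 0.300, 0.500),
    ("IH", "CPM+C"): (0.300, 0.500, 0.700),
    ("IH", "CPM+2C"): (0.700, 0.850, 1.000),
    ("IH", "CPPM"): (0.100, 0.300, 0.500),
    ("WO", "CPM"): (0.300, 0.500, 0.700),
    ("WO", "CPM+C"): (0.500, 0.750, 1.000),
    ("WO", "CPM+2C"): (0.500, 0.750, 1.000),
    ("WO", "CPPM"): (0.500, 0.750, 1.000),
}

#: Weighted normalised fuzzy decision matrix, 3 d.p.
EXPECTED_WEIGHTED = {
    ("QH", "CPM"): (0.000, 0.000, 0.050),
    ("QH", "CPM+C"): (0.090, 0.300, 0.500),
    ("QH", "CPM+2C"): (0.090, 0.300, 0.500),
    ("QH", "CPPM"): (0.070, 0.270, 0.500),
    ("MC", "CPM"): (0.000, 0.300, 0.500),
    ("MC", "CPM+C"): (0.000, 0.210, 0.450),
    ("MC", "CPM+2C"): (0.000, 0.180, 0.450),
    ("MC", "CPPM"): (0.000, 0.000, 0.050),
    ("IC", "CPM"): (0.000, 0.300, 0.500),
    ("IC", "CPM+C"): (0.000, 0.180, 0.450),
    ("IC", "CPM+2C"): (0.000, 0.030, 0.150),
    ("IC", "CPPM"): (0.000, 0.300, 0.500),
    ("MP", "CPM"): (0.000, 0.050, 0.210),
    ("MP", "CPM+C"): (0.000, 0.075, 0.300),
    ("MP", "CPM+2C"): (0.000, 0.075, 0.300),
    ("MP", "CPPM"): (0.000, 0.100, 0.300),
    ("IH", "CPM"): (0.000, 0.030, 0.150),
    ("IH", "CPM+C"): (0.000, 0.050, 0.210),
    ("IH", "CPM+2C"): (0.000, 0.085, 0.300),
    ("IH", "CPPM"): (0.000, 0.030, 0.150),
    ("WO", "CPM"): (0.000, 0.000, 0.070),
    ("WO", "CPM+C"): (0.000, 0.000, 0.100),
    ("WO", "CPM+2C"): (0.000, 0.000, 0.100),
    ("WO", "CPPM"): (0.000, 0.000, 0.100),
}

#: Final separations, closeness coefficients (3 d.p.) and ranks.
EXPECTED_RESULT = {
    "CPM": {"d_plus": 4.494, "d_minus": 1.805, "cc": 0.287, "rank": 4},
    "CPM+C": {"d_plus": 4.059, "d_minus": 2.314, "cc": 0.363, "rank": 3},
    "CPM+2C": {"d_plus": 3.824, "d_minus": 2.511, "cc": 0.396, "rank": 1},
    "CPPM": {"d_plus": 3.892, "d_minus": 2.404, "cc": 0.382, "rank": 2},
}

EXPECTED_RANKING = ("CPM+2C", "CPPM", "CPM+C", "CPM")
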