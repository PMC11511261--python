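import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from peonyforce.catalog import DEFAULT_CATALOG
from peonyforce.design import DEFAULT_DESIGN
from peonyforce.scoring import DEFAULT_RUBRIC
from peonyforce.synthetic import builtin_fixture
from peonyforce.table import TraitTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    return DEFAULT_CATALOG


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def rubric():
    return DEFAULT_RUBRIC


@pytest.fixture(scope="session")
def fixture_specs():
    return builtin_fixture()


@pytest.fixture(scope="session")
def fixture_lookup(fixture_specs):
    """(group_id, stage, trait) -> (mean, se, n)."""
    return {
        (s.group_id, s.stage, code): vals
        for s in fixture_specs
        for code, vals in s.traits.items()
    }


@pytest.fixture
def small_table():
    """Two plants, three defoliation traits."""
    rows = []
    for pid, (sl, sd, wpb) in {
        "p1": (100.0, 6.0, 300.0),
        "p2": (110.0, 6.4, 320.0),
    }.items():
        rows += [
            (pid, "T0", "defoliation", "SL", sl),
            (pid, "T0", "defoliation", "SD", sd),
            (pid, "T0", "defoliation", "WPB", wpb),
        ]
    return TraitTable.from_records(rows)


@pytest.fixture
def wide_csv(tmp_path):
    path = tmp_path / "wide.csv"
    pd.DataFrame(
        {
            "plant_id": ["p1", "p2"],
            "group_id": ["T0", "T0"],
            "stage": ["defoliation", "defoliation"],
            "SL": [100.0, 110.0],
            "SD": [6.0, 6.4],
            "WPB": [300.0, 320.0],
        }
    ).to_csv(path, index=False)
    return path
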