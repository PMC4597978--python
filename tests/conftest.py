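import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from cerepep import (
    Datastore,
    FixtureSpec,
    build_datastore,
    default_mass_table,
    default_rules,
    generate_fixture,
)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def mass_table():
    return default_mass_table()


@pytest.fixture(scope="session")
def fixture_set():
    """Seeded prolamin-like dataset with ground-truth manifest."""
    return generate_fixture(FixtureSpec(seed=1, n_proteins=10))


@pytest.fixture(scope="session")
def store(fixture_set) -> Datastore:
    """Full datastore built from the seeded fixture dataset."""
    return build_datastore(fixture_set.proteins, fixture_set.epitopes)
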