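import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from microleak.synthetic_data import default_study_config, generate_study
from microleak.tables_io import CountTable, RelativeAbundanceTable, to_relative

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> CountTable:
    return CountTable(pd.DataFrame(
        [[2, 3, 5], [1, 0, 9]],
        index=["S1", "S2"], columns=["Bacteroides", "Alistipes", "Akkermansia"],
    ))


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across tests (seed 7)."""
    table, metadata = generate_study(default_study_config(), seed=7)
    return table, metadata


@pytest.fixture(scope="session")
def study_pod4_rel(study):
    """POD4 relative abundances + metadata of known-outcome survivors."""
    table, metadata = study
    keep = [m for m in metadata
            if m.timepoint == "POD4" and m.al_status != "unknown"]
    ids = [m.sample_id for m in keep]
    rel = to_relative(table)
    return RelativeAbundanceTable(rel.data.loc[ids]), keep
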