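import numpy as np
import pandas as pd
import pytest

from upho.reasoner import forward_chain
from upho.scenario import scenario_graph, scenario_rules
from upho.semantics import default_scheme
from upho.tracts import GeneratorConfig, generate_tracts


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def default_table():
    """Synthetic Memphis-like table at the study's size (178 tracts)."""
    return generate_tracts(GeneratorConfig(seed=42))


@pytest.fixture()
def box_graph():
    """The worked patient-scenario graph, before inference."""
    return scenario_graph()


@pytest.fixture()
def box_closed():
    """The worked patient-scenario graph after forward chaining."""
    return forward_chain(scenario_graph(), scenario_rules())


@pytest.fixture()
def two_tract_table():
    return pd.DataFrame(
        {
            "geoid": ["47157000100", "47157000200"],
            "obesity_prev": [40.0, 30.0],
            "lack_physical_activity": [45.0, 25.0],
            "poverty": [50.0, 10.0],
            "no_hs_diploma": [15.0, 5.0],
            "unemployment": [20.0, 8.0],
            "pct_black": [80.0, 30.0],
            "lack_insurance": [25.0, 10.0],
            "low_access_supermarket": [1500.0, 1200.0],
            "crime_rate": [400.0, 200.0],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
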