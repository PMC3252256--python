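import numpy as np
import pytest

from wardstock import (
    AgentSpec,
    DDDReferenceTable,
    SimConfig,
    default_study_config,
    simulate,
)
from wardstock.simulate import OrderPolicy


@pytest.fixture
def unit_agent():
    """Agent whose pack is exactly one DDD, so packs == DDDs."""
    return AgentSpec("unit", "J01DC02", "unit drug", "parenteral",
                     ddd_mg=1000, pack_strength_mg=1000)


@pytest.fixture
def small_ref(unit_agent):
    oral = AgentSpec("unit_po", "J01MA02", "unit drug oral", "oral",
                     ddd_mg=1000, pack_strength_mg=1000)
    return DDDReferenceTable.from_agents([unit_agent, oral])


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated study, shared across tests."""
    return simulate(default_study_config(seed=12345))


@pytest.fixture(scope="session")
def default_ref(default_sim):
    return default_sim.config.reference_table()


def tiny_config(seed: int, weeks: int = 4, demand=(3.0, 10.0)) -> SimConfig:
    """Minimal 1-ward, 2-agent configuration for fuzzing."""
    agents = [
        AgentSpec("iv", "J01DC02", "iv drug", "parenteral",
                  ddd_mg=2000, pack_strength_mg=1000),
        AgentSpec("po", "J01MA02", "po drug", "oral",
                  ddd_mg=1000, pack_strength_mg=500),
    ]
    return SimConfig(
        wards=["w1"],
        agents=agents,
        demand={"w1": {"iv": demand[0], "po": demand[1]}},
        weeks=weeks,
        order_policy={
            "parenteral": OrderPolicy(3.0, (2.0, 3.0, 5.0)),
            "oral": OrderPolicy(5.0, (5.0, 10.0, 20.0)),
        },
        loan_in_rate=0.3,
        loan_out_rate=0.3,
        discard_rate=0.2,
        discharge_rate=0.3,
        return_rate=0.1,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
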