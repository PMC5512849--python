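import pytest

from aeroferm import (
    CultivationProtocol,
    DOSchedule,
    StrainSpec,
    load_network,
    load_parameters,
    simulate_batch,
)
from aeroferm.simulator import BatchSystem
from aeroferm.strains import apply_knockout


@pytest.fixture(scope="session")
def network():
    return load_network()


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def wt_system(network, params):
    return BatchSystem(*apply_knockout(network, params, StrainSpec.from_name("WT")))


def batch(strain="WT", do=40.0, glucose=10.0, biomass=0.1, t_max=120.0, **kwargs):
    protocol = CultivationProtocol(
        glucose_0=glucose,
        biomass_0=biomass,
        do_schedule=do if isinstance(do, DOSchedule) else DOSchedule.constant(do),
        strain=StrainSpec.from_name(strain),
        t_max=t_max,
    )
    return simulate_batch(protocol, **kwargs)


@pytest.fixture(scope="session")
def wt_aerobic_traj():
    """Completed aerobic wild-type batch (DO 40%), shared across tests."""
    return batch("WT", 40.0)


@pytest.fixture(scope="session")
def wt_microaerobic_traj():
    """Completed micro-aerobic wild-type batch (DO 1%)."""
    return batch("WT", 1.0)
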