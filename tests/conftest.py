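import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flysleep.network_topology import Topology
from flysleep.sim_engine import SimulationConfig, run_simulation

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_result():
    """One complete sleep/wake cycle on a 3x3 grid, compressed 4x in fast time.

    Small enough to run in seconds while still containing a complete sleep
    and a complete wake epoch after burn-in.
    """
    cfg = SimulationConfig(network={"kind": "grid", "n": 9},
                           duration=50.0, burn_in=24.0,
                           time_compression=0.25, seed=7)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def single_neuron_run():
    """A 0.3 s single-neuron run during closed-gate (sleep-like) conditions.

    Starting from [PER] > [dCLOCK], the gate stays closed for the first two
    model hours, so the membrane sees no circadian drive over this window.
    """
    topo = Topology(n=1, edges=frozenset())
    cfg = SimulationConfig(network=topo, duration=0.3, burn_in=0.0,
                           dclock0=0.1, per0=1.0, seed=3)
    return cfg, run_simulation(cfg)
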