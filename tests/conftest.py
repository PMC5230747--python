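import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from neurochip.simulator import CircuitSimulator
from neurochip.synthetic import make_fixture


@pytest.fixture(scope="session")
def adder4_registry():
    return make_fixture("adder4", seed=7)


@pytest.fixture(scope="session")
def counter3_registry():
    return make_fixture("counter3_decoder", seed=7)


@pytest.fixture(scope="session")
def microfsm_registry():
    return make_fixture("microfsm", seed=7)


@pytest.fixture(scope="session")
def microfsm_trace(microfsm_registry):
    sim = CircuitSimulator(microfsm_registry.netlist)
    return sim.run(microfsm_registry.behavior("hold").stimulus)


@pytest.fixture(scope="session")
def counter3_trace(counter3_registry):
    sim = CircuitSimulator(counter3_registry.netlist)
    return sim.run(counter3_registry.behavior("freerun").stimulus)
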