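import numpy as np
import pytest

import robfish as rf


@pytest.fixture(scope="session")
def demo_scenario():
    return rf.make_demo_scenario()


@pytest.fixture(scope="session")
def demo_result(demo_scenario):
    """One deterministic run of the Eastern Channel demo, shared by tests."""
    return rf.run_simulation(demo_scenario)


@pytest.fixture(scope="session")
def demo_space(demo_scenario):
    return demo_scenario.space()


@pytest.fixture(scope="session")
def box_records():
    """Campaign records from the box-recovery toy: success iff q1 < 0.4 and
    u1 > 0.3, with 1% of labels replaced by coin flips."""
    toy = rf.make_toy_scenario("box-recovery")
    return toy.records(n=5000, seed=42)


@pytest.fixture(scope="session")
def clean_box_records():
    """Noise-free box-recovery records (exactly separable labels)."""
    toy = rf.make_toy_scenario("box-recovery", noise=0.0)
    return toy.records(n=2000, seed=7)
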