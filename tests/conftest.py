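import numpy as np
import pytest

from ligandshell.core import build_mackay_core, trim_outer_layers
from ligandshell.forcefield import ParameterSet
from ligandshell.monolayer import init_random, make_plan


@pytest.fixture(scope="session")
def params():
    return ParameterSet.default()


@pytest.fixture(scope="session")
def core_k2():
    """Small core for engine tests: 42 anchor sites."""
    return trim_outer_layers(build_mackay_core(2), 2)


@pytest.fixture(scope="session")
def core_k3():
    return trim_outer_layers(build_mackay_core(3), 3)


@pytest.fixture(scope="session")
def core_k5():
    """The study core: k=5, outer three layers."""
    return trim_outer_layers(build_mackay_core(5), 3)


@pytest.fixture()
def micro_config(core_k2, params):
    """5-ligand mixed configuration for energy oracles."""
    plan = make_plan(0.4, l_total=5, paper_mode=False)
    return init_random(plan, core_k2, params, seed=42)


def jiggle(config, scale=0.15, seed=0):
    """Randomly perturb bead coordinates (sulfurs kept near their sites)."""
    rng = np.random.default_rng(seed)
    out = config.copy()
    out.coords += rng.normal(0.0, scale, out.coords.shape)
    return out
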