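import numpy as np
import pytest

from riscape.experiment import build_design, landscape_for, run_scenario
from riscape.fixtures import make_mini_config, make_toy_landscape
from riscape.simulator import run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def mini_state():
    """One completed miniature run (200 sites, 60 generations) shared by the
    invariant tests."""
    config = make_mini_config()
    landscape = make_toy_landscape("checkerboard", dims=(64, 64), block=16)
    return config, landscape, run_simulation(config, landscape)


@pytest.fixture(scope="session")
def desk_contrast_runs():
    """Paired desk-profile runs at D = 0.05, H = 0.9 across selection
    strengths s in {0, 0.02, 0.16, 0.64}, five replicates each.

    Pairs share the landscape, home sites and burn-in random numbers, so
    differences within a replicate isolate the effect of selection strength.
    """
    design = build_design("desk")
    rows = {}
    for rep in range(5):
        landscape = landscape_for(design, 0.9, rep, base_seed=1)
        for s in (0.0, 0.02, 0.16, 0.64):
            rows[(s, rep)] = run_scenario(
                design, 0.05, s, 0.9, rep, base_seed=1, landscape=landscape
            )
    return rows
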