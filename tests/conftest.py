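"""Shared fixtures.

The expensive end-to-end objects (a trained experiment-1 model with probe
decoding, the experiment-2 curves, the experiment-3 sweep) are built once
per session and shared by the acceptance tests; unit tests only touch the
cheap fixtures.
"""

import numpy as np
import pytest

from remapnet import ModelParams, Network
from remapnet.experiments import (ExperimentConfig, run_experiment_1,
                                  run_experiment_2, run_experiment_3)

#: Seed for every session-scoped simulation fixture.
SESSION_SEED = 1


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def net(params):
    """A freshly initialized (untrained) default network."""
    return Network.build(params, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def exp1(params):
    """Trained/untrained experiment-1 reports plus probe-decoded
    combination-preference correlations."""
    return run_experiment_1(ExperimentConfig(params=params,
                                             seed=SESSION_SEED),
                            decode_probe=True)


@pytest.fixture(scope="session")
def exp2(exp1, params):
    return run_experiment_2(exp1, ExperimentConfig(params=params,
                                                   seed=SESSION_SEED))


@pytest.fixture(scope="session")
def exp3(params):
    """Multidirection-remapping sweep at desk scale (three phi_C values)."""
    cfg = ExperimentConfig(params=params, seed=SESSION_SEED,
                           phi_C_sweep=(0.1, 0.5, 1.0))
    return run_experiment_3(cfg)
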