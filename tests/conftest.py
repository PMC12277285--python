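"""Shared fixtures.

The expensive fixtures (grown networks and protocol runs at reduced scale)
are session-scoped and shared by the qualitative acceptance tests; growing
a network once per seed and cloning it into each stimulation condition
keeps the full protocol grid affordable.

Two reduced-scale profiles are used.  The cheap ``test`` profile (500 E
neurons) covers comparisons driven by gross engram turnover.  Effects that
hinge on *partial* synapse deletion — the polarity-dependent modulation by
weak DC — need an equilibrium in-degree larger than the ~190 synapses the
fixed-amplitude learning input makes a neuron shed, and run on the denser
``dense`` profile (2000 E neurons, in-degree ~300).
"""

from __future__ import annotations

import numpy as np
import pytest

from hspsim.config import RunConfig, default_config
from hspsim.network import grow_network
from hspsim.protocols import run_experiment

#: seeds used for the rank-test comparisons of the protocol grid
SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def test_cfg() -> RunConfig:
    """Cheap reduced-scale accelerated profile."""
    return default_config("test")


@pytest.fixture(scope="session")
def dense_cfg() -> RunConfig:
    """Denser reduced-scale profile for partial-deletion effects."""
    return default_config("dense")


def _grow_all(cfg):
    return {seed: grow_network(cfg.replace(seed=seed),
                               seed_seq=np.random.SeedSequence(seed))
            for seed in SEEDS}


@pytest.fixture(scope="session")
def grown_nets(test_cfg):
    """One equilibrated cheap-profile network per seed (callers must clone)."""
    return _grow_all(test_cfg)


@pytest.fixture(scope="session")
def dense_nets(dense_cfg):
    """One equilibrated dense-profile network per seed (callers must clone)."""
    return _grow_all(dense_cfg)


def run_condition(base_cfg, nets, montage, timing, dvm, seeds=SEEDS, **kw):
    """Run one stimulation condition for several seeds off shared networks."""
    out = []
    for seed in seeds:
        cfg = base_cfg.replace(seed=seed, montage=montage, timing=timing,
                               delta_Vm_mV=dvm,
                               allow_strong=abs(dvm) > 0.6, **kw)
        out.append(run_experiment(cfg, sim=nets[seed]))
    return out


@pytest.fixture(scope="session")
def control_runs(test_cfg, grown_nets):
    """Learning with no tDCS (cheap profile): the reference engram."""
    return run_condition(test_cfg, grown_nets, "targeted", "none", 0.0)


@pytest.fixture(scope="session")
def dense_control_runs(dense_cfg, dense_nets):
    """Learning with no tDCS on the dense profile."""
    return run_condition(dense_cfg, dense_nets, "targeted", "none", 0.0)
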