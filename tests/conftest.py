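"""Shared fixtures.

Expensive artifacts (calibrated presets, ZAP simulations) are session-scoped
so that unit tests and the acceptance-criteria tests reuse one computation.
"""

import numpy as np
import pytest

from gapnet.trace import Trace
from gapnet.synthetic_models import (GapJunctionEdge, NetworkSpec,
                                     NeuronParams, make_preset,
                                     simulate_network)
from gapnet.stimuli import ZapSpec, generate_zap


@pytest.fixture()
def passive_cell():
    """Fast passive membrane: R_in = 200 MOhm, tau_m ~ 4 ms."""
    return NeuronParams(C=0.02, g_L=5.0, E_L=-65.0, g_w=0.0, tau_w=1.0)


@pytest.fixture()
def passive_pair(passive_cell):
    """Symmetric passive pair, g_c = 1.1 nS (closed-form CC 0.1803)."""
    return NetworkSpec([passive_cell, passive_cell.copy()],
                       [GapJunctionEdge(0, 1, 1.1)], seed=0)


@pytest.fixture(scope="session")
def rat_cell_preset():
    return make_preset("rat_cell")


@pytest.fixture(scope="session")
def mouse_cell_preset():
    return make_preset("mouse_cell")


@pytest.fixture(scope="session")
def rat_pair_preset():
    return make_preset("rat_pair")


@pytest.fixture(scope="session")
def rat_network_preset():
    return make_preset("rat_network", n_cells=10, seed=1)


@pytest.fixture(scope="session")
def mouse_network_preset():
    return make_preset("mouse_network", n_cells=10, seed=1)


def zap_run(cell, *, band_max=10.0, direction="ascending", dc=-20.0,
            duration=100.0):
    """Simulate the default ZAP into a single linear cell.

    Returns (V, I) traces at 1 kHz, both carrying the chirp metadata.
    """
    zap = generate_zap(ZapSpec(f_max=band_max, duration=duration,
                               direction=direction, dc_offset=dc))
    spec = NetworkSpec([cell], [], seed=0)
    ts = simulate_network(spec, {0: zap}, duration=zap.duration, dt=1e-3,
                          noise_on=False)
    v = ts.voltages[0]
    v.meta.update(zap.meta)
    i = Trace(zap.data[::10].copy(), 1e-3, "pA", "I", dict(zap.meta))
    return v, i


@pytest.fixture(scope="session")
def network_sync_run(rat_network_preset):
    """300 s noisy simulation of the strongly coupled 10-cell rat network
    and its uncoupled control (same cells, no edges)."""
    spec = rat_network_preset.resolved
    coupled = simulate_network(spec, duration=300.0, dt=1e-3, noise_on=True)
    uncoupled_spec = spec.copy()
    uncoupled_spec.edges = []
    uncoupled = simulate_network(uncoupled_spec, duration=300.0, dt=1e-3,
                                 noise_on=True)
    return coupled, uncoupled
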