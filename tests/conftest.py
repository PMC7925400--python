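"""Shared fixtures and helpers: tiny deterministic networks built in memory."""

import numpy as np
import pytest

from spikesim import ConnSpec, Network, SynSpec

# LIF parameters that keep neurons silent (delivery tests drive emissions
# by injection only)
SILENT = {"V_th": 1e9}


def make_relay_network(n_nodes, conn_triples, dt=0.1, seed=0,
                       record_deliveries=True):
    """Network of silent LIF nodes with an explicit connection list.

    ``conn_triples``: iterable of (src, tgt, weight, delay_ms).
    """
    net = Network(dt=dt, seed=seed, record_deliveries=record_deliveries)
    net.create("lif_psc_exp", n_nodes, params=SILENT)
    for src, tgt, w, d in conn_triples:
        net.connect([src], [tgt], ConnSpec(rule="one_to_one"),
                    SynSpec(weight=w, delay=d))
    net.calibrate()
    return net


def random_delivery_case(rng, max_nodes=100, max_delay_steps=20,
                         n_steps=500, dt=0.1):
    """Random small network + Poisson emission schedule for oracle tests.

    Returns (network, connections, emissions) where connections are
    (src, tgt, weight, delay_steps) and emissions are (step, node, mult).
    """
    n = int(rng.integers(2, max_nodes + 1))
    m = int(rng.integers(1, 4 * n))
    src = rng.integers(0, n, size=m)
    tgt = rng.integers(0, n, size=m)
    delay_steps = rng.integers(1, max_delay_steps + 1, size=m)
    weight = np.round(rng.uniform(0.5, 2.0, size=m), 3)
    net = Network(dt=dt, seed=int(rng.integers(2**31)),
                  record_deliveries=True)
    net.create("lif_psc_exp", n, params=SILENT)
    for s, t, w, d in zip(src, tgt, weight, delay_steps):
        net.connect([s], [t], ConnSpec(rule="one_to_one"),
                    SynSpec(weight=float(w), delay=float(d) * dt))
    net.calibrate()
    # Poisson-ish drive: each node emits with small probability per step
    p = rng.uniform(0.002, 0.02)
    emissions = []
    conns = list(zip(src.tolist(), tgt.tolist(), weight.tolist(),
                     delay_steps.tolist()))
    return net, conns, emissions, p


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
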