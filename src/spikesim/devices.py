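"""Stimulation and recording devices.

Poisson generators are spiking nodes wired through the same buffer/connection
machinery as neurons.  Two delivery semantics are available:

* independent (default): every generator-to-target connection receives its
  own Poisson realization, equivalent to one private generator per target —
  the semantics the benchmark networks assume;
* shared: a single realization per step is pushed through the generator's
  spike buffer and fans out to all targets with one multiplicity.

Recorders are passive: they copy emission events (spike recorder) or sampled
state variables (multimeter) and never feed back into the simulation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PoissonGenerator", "SpikeRecorder", "Multimeter"]


class PoissonGenerator:
    """Poisson spike source with per-step mean ``rate * dt / 1000``."""

    model_tag = "poisson_generator"

    def __init__(self, rate, node_id, rng, independent=True):
        if rate < 0:
            raise ValueError("Poisson rate must be non-negative")
        self.rate = float(rate)
        self.node_id = int(node_id)
        self.rng = rng
        self.independent = independent
        self._groups = None

    def calibrate(self, store, dt):
        self.dt = dt
        self.lam = self.rate * dt / 1000.0
        g0 = store.node_group_start[self.node_id]
        ng = store.node_group_count[self.node_id]
        self._groups = [(int(store.group_delay[g]),
                         int(store.group_conn_start[g]),
                         int(store.group_conn_end[g]))
                        for g in range(g0, g0 + ng)]

    def emit(self, step, network):
        """Draw this step's spikes and hand them to the delivery machinery."""
        if self.lam == 0.0:
            return
        if self.independent:
            for delay, c0, c1 in self._groups:
                mult = self.rng.poisson(self.lam, size=c1 - c0)
                nz = np.flatnonzero(mult)
                if nz.size:
                    network.schedule_connection_events(
                        step + delay, c0 + nz, mult[nz])
        else:
            m = int(self.rng.poisson(self.lam))
            if m > 0:
                network.push_device_spike(self.node_id, m)


class SpikeRecorderLog:
    """Flat (sender id, spike time ms) event log."""

    def __init__(self):
        self.senders = []
        self.times = []

    def append(self, senders, time_ms):
        self.senders.append(np.asarray(senders, dtype=np.int64))
        self.times.append(np.full(len(senders), time_ms))

    def as_arrays(self):
        if not self.senders:
            return np.zeros(0, dtype=np.int64), np.zeros(0)
        return np.concatenate(self.senders), np.concatenate(self.times)


class SpikeRecorder:
    """Records (sender, time) for a set of node ids (or every node)."""

    def __init__(self, nodes=None):
        self.nodes = None if nodes is None else np.asarray(nodes, dtype=np.int64)
        self._set = None if nodes is None else set(int(i) for i in self.nodes)
        self.log = SpikeRecorderLog()

    def record(self, senders, time_ms):
        if self.nodes is not None:
            senders = [s for s in senders if int(s) in self._set]
        if len(senders):
            self.log.append(senders, time_ms)

    def events(self):
        return self.log.as_arrays()

    def spike_trains(self):
        """Events regrouped as {sender: sorted time array}."""
        senders, times = self.events()
        out = {}
        order = np.argsort(senders, kind="stable")
        senders, times = senders[order], times[order]
        if senders.size == 0:
            return out
        brk = np.flatnonzero(np.diff(senders)) + 1
        for chunk_s, chunk_t in zip(np.split(senders, brk),
                                    np.split(times, brk)):
            out[int(chunk_s[0])] = np.sort(chunk_t)
        return out


class Multimeter:
    """Samples one state variable of a population at a fixed interval."""

    def __init__(self, population, variable, interval_steps=1):
        self.population = population
        self.variable = variable
        self.interval = int(interval_steps)
        self.times = []
        self.values = []

    def maybe_sample(self, step, time_ms):
        if step % self.interval == 0:
            self.times.append(time_ms)
            self.values.append(self.population.get_state(self.variable).copy())

    def as_arrays(self):
        return np.asarray(self.times), np.asarray(self.values)
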