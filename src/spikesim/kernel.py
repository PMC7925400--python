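"""Simulation kernel: network container, time grid, and the per-step loop.

The loop order within one step (advancing the network from t to t + dt) is

1. advance spike buffers; matured spikes fill the global spike array;
2. deliver the spike array to target input accumulators (presynaptic-side
   plasticity runs here, at arrival time);
3. update devices; device spikes enter their buffers / delivery schedule;
4. update neuron dynamics over one dt using the delivered input;
5. threshold handling: resets, pushes into the emitters' spike buffers,
   postsynaptic-side plasticity;
6. recording.

Delivery precedes the dynamics update, so a spike emitted at step t on a
connection with delay d (in steps, minimum 1) influences its target's
dynamics during step t + d.  Spike emission and arrival times are stamped on
the grid as (step + 1) * dt — the end of the step in which they occur.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field

import numpy as np

from . import plasticity
from .connect import ConnSpec, SynSpec, ConnectionList, connect as _connect
from .devices import Multimeter, PoissonGenerator, SpikeRecorder
from .neuron_models import (AdExPopulation, IzhikevichPopulation,
                            LIFPopulation, PopulationBase)
from .spike_delivery import ConnectionStore, SpikeBufferTable, deliver

__all__ = ["Network", "TimeGrid", "SimulationReport", "ConfigurationError"]

log = logging.getLogger(__name__)

MODEL_CLASSES = {
    "lif_psc_exp": LIFPopulation,
    "aeif_cond_beta": AdExPopulation,
    "izhikevich": IzhikevichPopulation,
}


class ConfigurationError(RuntimeError):
    pass


@dataclass
class TimeGrid:
    """Drift-free biological clock: time is always step_index * dt."""
    dt: float
    step_index: int = 0

    @property
    def biological_time(self):
        return self.step_index * self.dt


@dataclass
class SimulationReport:
    steps: int = 0
    spikes_emitted: int = 0          # emission events (buffer pushes)
    spike_array_events: int = 0      # (source, group) deliveries staged
    spikes_delivered: int = 0        # single-connection deliveries
    max_spike_array_occupancy: int = 0
    duration_ms: float = 0.0
    wall_time_s: float = 0.0


class Network:
    """Container for populations, devices, connections, and the time grid.

    One base seed drives the whole run; device substreams are derived
    deterministically from (seed, device index) so the presence of one
    device never perturbs another's draws or the connectivity realization.
    """

    def __init__(self, dt=0.1, seed=12345, record_deliveries=False):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = TimeGrid(dt=dt)
        self.seed = int(seed)
        self.populations: list[PopulationBase] = []
        self.devices: list[PoissonGenerator] = []
        self.recorders: list[SpikeRecorder] = []
        self.multimeters: list[Multimeter] = []
        self._n_nodes = 0
        self._conn_builder = ConnectionList()
        self._calibrated = False
        self.store: ConnectionStore | None = None
        self.buffers: SpikeBufferTable | None = None
        self._pending = {}        # step -> [(conn_ids, mults)] device events
        self._post_queue = {}     # step -> [(conn_ids, targets, t_eff)]
        self.report = SimulationReport()
        self.delivery_log = [] if record_deliveries else None
        self._build_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(0,)))
        self._init_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(2,)))

    # ------------------------------------------------------------------
    # construction
    @property
    def dt(self):
        return self.grid.dt

    @property
    def n_nodes(self):
        return self._n_nodes

    @property
    def step_index(self):
        return self.grid.step_index

    def _claim_ids(self, n):
        first = self._n_nodes
        self._n_nodes += n
        return first

    def create(self, model, n=1, params=None, **kwargs) -> PopulationBase:
        """Add a homogeneous neuron population; returns the population."""
        if self._calibrated:
            raise ConfigurationError("network already calibrated")
        cls = MODEL_CLASSES.get(model, model)
        if not (isinstance(cls, type) and issubclass(cls, PopulationBase)):
            raise ConfigurationError(f"unknown neuron model {model!r}")
        pop = cls(n, params=params, first_id=self._claim_ids(n), **kwargs)
        self.populations.append(pop)
        return pop

    def create_poisson_generator(self, rate, independent=True):
        if self._calibrated:
            raise ConfigurationError("network already calibrated")
        node_id = self._claim_ids(1)
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(1, len(self.devices))))
        dev = PoissonGenerator(rate, node_id, rng, independent=independent)
        self.devices.append(dev)
        return dev

    @staticmethod
    def _ids_of(group):
        if isinstance(group, PopulationBase):
            return group.ids
        if isinstance(group, PoissonGenerator):
            return np.array([group.node_id])
        return np.asarray(group, dtype=np.int64)

    def connect(self, pre, post, conn_spec=None, syn_spec=None):
        """Wire two node groups; specs may be dataclasses or plain dicts."""
        if self._calibrated:
            raise ConfigurationError(
                "cannot add connections after calibration")
        conn = conn_spec if isinstance(conn_spec, ConnSpec) \
            else ConnSpec(**(conn_spec or {}))
        syn = syn_spec if isinstance(syn_spec, SynSpec) \
            else SynSpec(**(syn_spec or {}))
        src, tgt, w, d = _connect(self._ids_of(pre), self._ids_of(post),
                                  conn, syn, self._build_rng, self.dt)
        self._conn_builder.extend(src, tgt, w, d, syn)

    def record_spikes(self, nodes=None):
        rec = SpikeRecorder(None if nodes is None else self._ids_of(nodes))
        self.recorders.append(rec)
        return rec

    def add_multimeter(self, population, variable, interval_steps=1):
        mm = Multimeter(population, variable, interval_steps)
        self.multimeters.append(mm)
        return mm

    @property
    def init_rng(self):
        """Stream reserved for state initialization (membrane potentials...)."""
        return self._init_rng

    # ------------------------------------------------------------------
    # calibration
    def calibrate(self):
        """Quantize delays, build delay-sorted connection groups and buffers.

        Idempotent; called automatically by :meth:`simulate`.
        """
        if self._calibrated:
            return self
        if self._n_nodes == 0:
            raise ConfigurationError("network has no nodes")
        self.store = ConnectionStore(self._conn_builder, self._n_nodes,
                                     self.dt)
        self.buffers = SpikeBufferTable(self.store)
        self._max_ports = max([p.n_ports for p in self.populations],
                              default=1)
        self._arrivals = np.zeros((self._n_nodes, self._max_ports))
        self._arrivals_flat = self._arrivals.reshape(-1)
        for pop in self.populations:
            pop.calibrate(self.dt)
        for dev in self.devices:
            dev.calibrate(self.store, self.dt)
        self._calibrated = True
        return self

    # ------------------------------------------------------------------
    # event plumbing used by devices and tests
    def schedule_connection_events(self, at_step, conn_ids, mults):
        """Schedule per-connection deliveries (independent-realization path)."""
        self._pending.setdefault(at_step, []).append(
            (np.asarray(conn_ids, dtype=np.int64),
             np.asarray(mults, dtype=np.int64)))

    def push_device_spike(self, node_id, multiplicity):
        self._emit(np.array([node_id]), np.array([multiplicity]))

    def inject_spike(self, node, multiplicity=1):
        """Force an emission from ``node`` as if it had fired this step.

        Debug/testing hook: the spike enters the node's buffer immediately
        and is delivered after the connection delays, exactly like a
        threshold-triggered spike.
        """
        if not self._calibrated:
            raise ConfigurationError("calibrate the network first")
        # between steps the pending step index is step_index, so the spike
        # behaves like a phase-5 emission of the step that just completed
        self._emit(np.array([int(node)]), np.array([int(multiplicity)]),
                   t_event=self.grid.step_index * self.dt)

    # ------------------------------------------------------------------
    # the step loop
    def _emit(self, ids, mults=None, t_event=None):
        """Phase-5 bookkeeping for emitted spikes (also used by devices)."""
        if t_event is None:
            t_event = (self.grid.step_index + 1) * self.dt
        self.report.spikes_emitted += len(ids)
        self.buffers.push(ids, mults)
        for rec in self.recorders:
            rec.record(ids, t_event)
        st = self.store
        if st.in_stdp_conn.size:
            conns = st.incoming_stdp(ids)
            if conns.size:
                dsteps = st.dend_steps[conns]
                for d in np.unique(dsteps):
                    sub = conns[dsteps == d]
                    t_eff = t_event + d * self.dt
                    if d == 0:
                        plasticity.apply_post_spike(
                            st.weight, sub, t_eff, st.last_pre,
                            st.stdp_param_sets, st.param_set)
                    else:
                        self._post_queue.setdefault(
                            self.grid.step_index + int(d), []).append(
                                (sub, np.unique(st.target[sub]), t_eff))
            st.last_post_effect[ids] = t_event

    def _deliver_pending(self, s, t_event):
        batches = self._pending.pop(s, None)
        if not batches:
            return
        st = self.store
        for conn_ids, mults in batches:
            tgt = st.target[conn_ids]
            amounts = st.weight[conn_ids] * mults
            key = tgt * self._max_ports + st.port[conn_ids]
            self._arrivals_flat += np.bincount(
                key, weights=amounts, minlength=self._arrivals_flat.size)
            smask = st.is_stdp[conn_ids]
            if smask.any():
                plasticity.apply_pre_arrival(
                    st.weight, conn_ids[smask], t_event, tgt[smask],
                    st.last_pre, st.last_post_effect,
                    st.stdp_param_sets, st.param_set)
            self.report.spikes_delivered += int(mults.sum())

    def step(self):
        """Run a single simulation step (one dt of biological time)."""
        if not self._calibrated:
            raise ConfigurationError("calibrate the network first")
        s = self.grid.step_index
        t_event = (s + 1) * self.dt
        rep = self.report

        # 1-2: buffer advancement, spike array, delivery
        self._arrivals[:] = 0.0
        ev = self.buffers.advance()
        n_ev = ev[0].size
        rep.spike_array_events += n_ev
        rep.max_spike_array_occupancy = max(
            rep.max_spike_array_occupancy, n_ev)
        dlog = [] if self.delivery_log is not None else None
        rep.spikes_delivered += deliver(ev, self.store, self._arrivals_flat,
                                        self._max_ports, t_event, dlog)
        if dlog is not None:
            for srcs, tgts, amounts in dlog:
                self.delivery_log.append((s, srcs, tgts, amounts))
        self._deliver_pending(s, t_event)

        # 3: devices
        for dev in self.devices:
            dev.emit(s, self)

        # 4-5: neuron dynamics, thresholds, emission
        for pop in self.populations:
            arr = self._arrivals[pop.first_id:pop.first_id + pop.n,
                                 :pop.n_ports]
            spiked = pop.update(arr, self.dt)
            if spiked.any():
                self._emit(pop.ids[spiked])
        for conns, targets, t_eff in self._post_queue.pop(s, []):
            plasticity.apply_post_spike(
                self.store.weight, conns, t_eff, self.store.last_pre,
                self.store.stdp_param_sets, self.store.param_set)
            self.store.last_post_effect[targets] = t_eff

        # 6: recording devices that sample state
        for mm in self.multimeters:
            mm.maybe_sample(s, t_event)
        self.grid.step_index += 1

    def simulate(self, duration, progress_every=None):
        """Run ``round(duration / dt)`` steps; returns the cumulative report.

        ``progress_every`` (ms) logs step progress to standard error.
        """
        if duration < 0:
            raise ValueError("duration must be non-negative")
        self.calibrate()
        n_steps = int(round(duration / self.dt))
        every = (max(1, int(round(progress_every / self.dt)))
                 if progress_every else None)
        t0 = time.perf_counter()
        for i in range(n_steps):
            self.step()
            if every and (i + 1) % every == 0:
                print(f"[spikesim] t = {self.grid.biological_time:.1f} ms "
                      f"({i + 1}/{n_steps} steps)", file=sys.stderr)
        self.report.steps += n_steps
        self.report.duration_ms += n_steps * self.dt
        self.report.wall_time_s += time.perf_counter() - t0
        return self.report
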