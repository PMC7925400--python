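"""Spike buffers, delay-sorted connection groups, and the global spike array.

Every node (neuron or spiking device) owns one output spike buffer.  A spike
is stored in the buffer as just three numbers: a multiplicity, a time index
``t_s`` (steps since emission, starting at 0), and a connection-group index
``i_g`` (the next group to serve, starting at 0).  The node's outgoing
connections are partitioned into groups of equal quantized delay, sorted in
ascending delay order.  Each step every live entry's ``t_s`` is incremented;
when it equals the delay of group ``i_g`` the spike is staged on the global
spike array for that group and ``i_g`` advances.  Because groups are
delay-sorted, one comparison per entry per step suffices — no nested loop
over groups.  Entries that have served their last group are discarded.

The buffers of all nodes are held in one struct-of-arrays table so that
advancement and delivery are vectorized over live entries; per-node views
(:meth:`SpikeBufferTable.entries_for`) expose the per-buffer semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import plasticity

__all__ = ["ConnectionStore", "SpikeBufferTable", "SpikeBufferEntry",
           "SpikeArrayEvent", "multi_arange", "deliver"]


def multi_arange(starts, lengths):
    """Concatenate ``arange(s, s+l)`` for paired start/length arrays (vectorized)."""
    lengths = np.asarray(lengths, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    total = int(lengths.sum())
    if total == 0:
        return np.zeros(0, dtype=np.int64)
    keep = lengths > 0
    starts, lengths = starts[keep], lengths[keep]
    steps = np.ones(total, dtype=np.int64)
    steps[0] = starts[0]
    ends = np.cumsum(lengths)
    steps[ends[:-1]] = starts[1:] - (starts[:-1] + lengths[:-1] - 1)
    return np.cumsum(steps)


@dataclass
class SpikeBufferEntry:
    """One buffered spike: multiplicity, age in steps, next group to serve."""
    multiplicity: int
    t_s: int
    i_g: int


@dataclass
class SpikeArrayEvent:
    """One staged delivery: a (source, connection-group) pair plus multiplicity."""
    source: int
    group: int          # global group id
    multiplicity: int


class ConnectionStore:
    """Calibrated, delay-sorted connection table in CSR-like layout.

    Connections are sorted by (source, delay) and partitioned into groups of
    identical quantized delay.  ``node_group_start``/``node_group_count``
    index each node's contiguous run of groups; ``group_conn_start``/``end``
    index each group's contiguous run of connections.
    """

    def __init__(self, conn_list, n_nodes, dt):
        (src, tgt, weight, delay_ms, port, kind,
         param_set, dend_delay) = conn_list.concatenated()
        if tgt.size and (tgt.min() < 0 or tgt.max() >= n_nodes):
            raise RuntimeError("dangling target id in connection table")
        # round-half-up quantization with a 1-step floor
        delay_steps = np.floor(delay_ms / dt + 0.5).astype(np.int64)
        n_clipped = int(np.count_nonzero(delay_steps < 1))
        if n_clipped:
            import logging
            logging.getLogger(__name__).warning(
                "%d connection delays below one step clipped to 1", n_clipped)
            delay_steps = np.maximum(delay_steps, 1)

        # sort by (source, delay); composite key is faster than lexsort and
        # intra-group connection order is immaterial
        max_d = int(delay_steps.max()) + 1 if delay_steps.size else 1
        order = np.argsort(src * max_d + delay_steps)
        self.source = src[order]
        self.target = tgt[order]
        self.weight = weight[order]
        self.delay_steps = delay_steps[order]
        self.port = port[order]
        self.is_stdp = kind[order].astype(bool)
        self.param_set = param_set[order]
        self.dend_steps = np.floor(dend_delay[order] / dt + 0.5).astype(np.int64)
        self.stdp_param_sets = list(conn_list.stdp_param_sets)
        self.n_nodes = n_nodes
        self.n_connections = self.source.size

        # group boundaries: change of source or delay
        if self.n_connections:
            brk = np.flatnonzero(
                (np.diff(self.source) != 0) | (np.diff(self.delay_steps) != 0))
            self.group_conn_start = np.concatenate(([0], brk + 1))
            self.group_conn_end = np.concatenate(
                (brk + 1, [self.n_connections]))
        else:
            self.group_conn_start = np.zeros(0, dtype=np.int64)
            self.group_conn_end = np.zeros(0, dtype=np.int64)
        self.group_source = self.source[self.group_conn_start] \
            if self.n_connections else np.zeros(0, dtype=np.int64)
        self.group_delay = self.delay_steps[self.group_conn_start] \
            if self.n_connections else np.zeros(0, dtype=np.int64)
        self.n_groups = self.group_source.size

        counts = np.bincount(self.group_source, minlength=n_nodes) \
            if self.n_groups else np.zeros(n_nodes, dtype=np.int64)
        self.node_group_count = counts.astype(np.int64)
        self.node_group_start = np.concatenate(
            ([0], np.cumsum(counts)[:-1])).astype(np.int64)
        # last-group delay per node (0 where no outputs): buffer lifetime bound
        self.node_max_delay = np.zeros(n_nodes, dtype=np.int64)
        if self.n_groups:
            last = self.node_group_start + self.node_group_count - 1
            has = self.node_group_count > 0
            self.node_max_delay[has] = self.group_delay[last[has]]

        # plasticity state
        self.last_pre = np.full(self.n_connections, np.nan)
        self.last_post_effect = np.full(n_nodes, np.nan)
        # reverse CSR over incoming stdp connections, per target
        sidx = np.flatnonzero(self.is_stdp)
        if sidx.size:
            rorder = np.argsort(self.target[sidx], kind="stable")
            self.in_stdp_conn = sidx[rorder]
            cnt = np.bincount(self.target[sidx], minlength=n_nodes)
            self.in_stdp_ptr = np.concatenate(([0], np.cumsum(cnt)))
        else:
            self.in_stdp_conn = np.zeros(0, dtype=np.int64)
            self.in_stdp_ptr = np.zeros(n_nodes + 1, dtype=np.int64)

    def groups_of(self, node):
        """Delay-sorted (delay_steps, connection-index-array) pairs of one node."""
        g0 = self.node_group_start[node]
        out = []
        for g in range(g0, g0 + self.node_group_count[node]):
            out.append((int(self.group_delay[g]),
                        np.arange(self.group_conn_start[g],
                                  self.group_conn_end[g])))
        return out

    def incoming_stdp(self, nodes):
        """Global ids of plastic connections targeting the given nodes."""
        starts = self.in_stdp_ptr[nodes]
        lens = self.in_stdp_ptr[np.asarray(nodes) + 1] - starts
        return self.in_stdp_conn[multi_arange(starts, lens)]


class SpikeBufferTable:
    """All nodes' output spike buffers, stored as one growable entry table."""

    def __init__(self, store: ConnectionStore):
        self.store = store
        self.src = np.zeros(0, dtype=np.int64)
        self.t_s = np.zeros(0, dtype=np.int64)
        self.i_g = np.zeros(0, dtype=np.int64)
        self.mult = np.zeros(0, dtype=np.int64)

    @property
    def n_entries(self):
        return self.src.size

    def entries_for(self, node):
        """Per-node buffer view, as a list of :class:`SpikeBufferEntry`."""
        sel = np.flatnonzero(self.src == node)
        return [SpikeBufferEntry(int(self.mult[i]), int(self.t_s[i]),
                                 int(self.i_g[i])) for i in sel]

    def push(self, nodes, mults=None):
        """Insert spikes (t_s = 0, i_g = 0) for the given emitting nodes.

        Nodes with no outgoing connection groups are dropped immediately.
        Same-step duplicates (an existing entry with t_s == 0) are merged by
        summing multiplicities, preserving the at-most-one-event-per-group-
        per-step invariant.
        """
        nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
        if mults is None:
            mults = np.ones(nodes.size, dtype=np.int64)
        else:
            mults = np.atleast_1d(np.asarray(mults, dtype=np.int64))
        if np.any(mults < 1):
            raise ValueError("spike multiplicity must be >= 1")
        keep = self.store.node_group_count[nodes] > 0
        nodes, mults = nodes[keep], mults[keep]
        if nodes.size == 0:
            return
        fresh = np.flatnonzero(self.t_s == 0)
        if fresh.size:
            pos = {int(s): int(i) for i, s in zip(fresh, self.src[fresh])}
            new_nodes, new_mults = [], []
            for n, m in zip(nodes, mults):
                if int(n) in pos:
                    self.mult[pos[int(n)]] += m
                else:
                    new_nodes.append(n)
                    new_mults.append(m)
            nodes = np.asarray(new_nodes, dtype=np.int64)
            mults = np.asarray(new_mults, dtype=np.int64)
            if nodes.size == 0:
                return
        self.src = np.concatenate((self.src, nodes))
        self.t_s = np.concatenate((self.t_s, np.zeros(nodes.size, dtype=np.int64)))
        self.i_g = np.concatenate((self.i_g, np.zeros(nodes.size, dtype=np.int64)))
        self.mult = np.concatenate((self.mult, mults))

    def advance(self):
        """Age every live entry by one step and stage matured spikes.

        Returns the spike array for this step as three parallel arrays
        ``(sources, global_group_ids, multiplicities)``.  Entries whose group
        index has passed the last group are removed (swap-free compaction;
        entry order is immaterial since each carries its own age).
        """
        st = self.store
        if self.src.size == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z, z
        self.t_s += 1
        gidx = st.node_group_start[self.src] + self.i_g
        hit = self.t_s == st.group_delay[gidx]
        ev_src = self.src[hit]
        ev_group = gidx[hit]
        ev_mult = self.mult[hit]
        self.i_g[hit] += 1
        alive = self.i_g < st.node_group_count[self.src]
        if not alive.all():
            self.src = self.src[alive]
            self.t_s = self.t_s[alive]
            self.i_g = self.i_g[alive]
            self.mult = self.mult[alive]
        return ev_src, ev_group, ev_mult


def deliver(events, store: ConnectionStore, acc_flat, n_ports, t_now,
            delivery_log=None):
    """Send staged spike-array events to their target input accumulators.

    ``acc_flat`` is the flattened (n_nodes, n_ports) accumulator; each
    connection adds ``weight * multiplicity`` to its target's receptor port.
    Plastic connections additionally run presynaptic-side pairing with
    arrival time ``t_now``.  Returns the number of spike deliveries
    performed (multiplicity-weighted).
    """
    ev_src, ev_group, ev_mult = events
    if ev_group.size == 0:
        return 0
    starts = store.group_conn_start[ev_group]
    lens = store.group_conn_end[ev_group] - starts
    idx = multi_arange(starts, lens)
    rep_mult = np.repeat(ev_mult, lens)
    tgt = store.target[idx]
    amounts = store.weight[idx] * rep_mult
    key = tgt * n_ports + store.port[idx]
    acc_flat += np.bincount(key, weights=amounts, minlength=acc_flat.size)
    if delivery_log is not None:
        delivery_log.append((store.source[idx].copy(), tgt.copy(),
                             amounts.copy()))
    smask = store.is_stdp[idx]
    if smask.any():
        sids = idx[smask]
        plasticity.apply_pre_arrival(
            store.weight, sids, t_now, tgt[smask], store.last_pre,
            store.last_post_effect, store.stdp_param_sets, store.param_set)
    return int(rep_mult.sum())
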