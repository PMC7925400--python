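"""Spike buffer semantics, connection grouping, and delivery correctness."""

from collections import Counter

import numpy as np
import pytest

from spikesim import ConnSpec, Network, SynSpec
from spikesim.spike_delivery import multi_arange
from spikesim.oracle import oracle_deliveries

from conftest import SILENT, make_relay_network, random_delivery_case


def run_with_injections(net, emissions, n_steps):
    """Drive a silent network by injecting the given (step, node, mult)."""
    by_step = {}
    for step, node, mult in emissions:
        by_step.setdefault(step, []).append((node, mult))
    for s in range(n_steps):
        net.step()
        for node, mult in by_step.get(s, []):
            net.inject_spike(node, mult)


def delivery_multiset(net, n_steps):
    out = Counter()
    for step, srcs, tgts, amounts in net.delivery_log:
        for s, t, a in zip(srcs, tgts, amounts):
            if step < n_steps:
                out[(int(s), int(t), int(step), float(a))] += 1
    return out


class TestMultiArange:
    def test_concatenated_ranges(self):
        got = multi_arange([2, 10, 5], [3, 0, 2])
        assert got.tolist() == [2, 3, 4, 5, 6]

    def test_empty(self):
        assert multi_arange([], []).size == 0


class TestBufferSemantics:
    def test_push_creates_entry_with_zero_age(self):
        net = make_relay_network(3, [(0, 1, 1.0, 0.2), (0, 2, 1.0, 0.5)])
        net.inject_spike(0)
        (entry,) = net.buffers.entries_for(0)
        assert (entry.multiplicity, entry.t_s, entry.i_g) == (1, 0, 0)

    def test_no_outputs_discards_spike(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.2)])
        net.inject_spike(1)  # node 1 has no outgoing groups
        assert net.buffers.n_entries == 0

    def test_successive_pushes_coexist_with_distinct_ages(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.5)])
        net.inject_spike(0)
        net.step()
        net.inject_spike(0)
        ages = sorted(e.t_s for e in net.buffers.entries_for(0))
        assert ages == [0, 1]

    def test_same_step_pushes_merge_multiplicity(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.5)])
        net.inject_spike(0, 2)
        net.inject_spike(0, 3)
        (entry,) = net.buffers.entries_for(0)
        assert entry.multiplicity == 5

    def test_multiplicity_below_one_rejected(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.5)])
        with pytest.raises(ValueError):
            net.inject_spike(0, 0)

    def test_entry_serves_groups_in_delay_order_then_dies(self):
        # groups at 2 and 5 steps; events exactly at ages 2 and 5
        net = make_relay_network(2, [(0, 1, 1.0, 0.2), (0, 1, 2.0, 0.5)])
        net.inject_spike(0)
        hits = []
        for s in range(8):
            before = net.report.spike_array_events
            net.step()
            if net.report.spike_array_events > before:
                hits.append(s)
        assert hits == [1, 4]  # ages 2 and 5 reached at these steps
        assert net.buffers.n_entries == 0

    def test_single_group_minimum_delay(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.1)])
        net.inject_spike(0)
        net.step()
        assert net.buffers.n_entries == 0
        assert net.report.spike_array_events == 1


class TestConnectionGroups:
    def test_groups_partition_by_quantized_delay(self):
        # delays 0.5, 0.5, 1.2 ms at dt=0.1 -> two groups: 5 and 12 steps
        net = make_relay_network(
            4, [(0, 1, 1.0, 0.5), (0, 2, 1.0, 0.5), (0, 3, 1.0, 1.2)])
        groups = net.store.groups_of(0)
        assert [g[0] for g in groups] == [5, 12]
        assert [len(g[1]) for g in groups] == [2, 1]

    def test_subdt_delay_clipped_to_one_step(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.04)])
        assert net.store.groups_of(0)[0][0] == 1

    def test_node_without_outputs_has_zero_groups(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.5)])
        assert net.store.groups_of(1) == []

    def test_group_delays_strictly_increase(self, rng):
        net, conns, _, _ = random_delivery_case(rng)
        for node in range(net.populations[0].n):
            delays = [d for d, _ in net.store.groups_of(node)]
            assert delays == sorted(delays)
            assert len(set(delays)) == len(delays)


class TestDelivery:
    def test_amplitude_scales_with_weight_and_multiplicity(self):
        triples = [(0, i, 0.05, 0.3) for i in (1, 2, 3)]
        net = make_relay_network(4, triples)
        net.inject_spike(0, 2)
        for _ in range(3):
            net.step()
        # each of 3 targets accumulated weight x multiplicity = 0.10 into
        # I_syn (decayed once by the step in which it arrived)
        pop = net.populations[0]
        decay = np.exp(-net.dt / 0.5)
        assert np.allclose(pop.I_syn[1:], 0.10 * decay)

    def test_convergent_sources_sum(self):
        net = make_relay_network(3, [(0, 2, 1.5, 0.3), (1, 2, 2.0, 0.3)])
        net.inject_spike(0)
        net.inject_spike(1)
        for _ in range(3):
            net.step()
        (step, srcs, tgts, amounts) = net.delivery_log[-1]
        assert sorted(amounts.tolist()) == [1.5, 2.0]
        assert set(tgts.tolist()) == {2}

    def test_empty_event_list_no_state_change(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.5)])
        v0 = net.populations[0].V_m.copy()
        net.step()
        assert np.array_equal(net.populations[0].V_m, v0)
        assert net.report.spikes_delivered == 0


class TestOracleEquivalence:
    """Spike-buffer path vs independent event-queue reference."""

    def test_single_connection_delay(self):
        net = make_relay_network(2, [(0, 1, 1.0, 0.7)])
        run_with_injections(net, [(3, 0, 1)], 20)
        got = delivery_multiset(net, 20)
        want = oracle_deliveries([(0, 1, 1.0, 7)], [(3, 0, 1)], 20)
        assert got == want

    def test_equal_delays_single_group(self):
        conns = [(0, t, 1.0, 0.4) for t in (1, 2, 3)]
        net = make_relay_network(4, conns)
        run_with_injections(net, [(0, 0, 1), (5, 0, 2)], 30)
        want = oracle_deliveries([(0, t, 1.0, 4) for t in (1, 2, 3)],
                                 [(0, 0, 1), (5, 0, 2)], 30)
        assert delivery_multiset(net, 30) == want

    def test_randomized_networks_match_event_queue(self):
        """Delivered (source, target, step, amount) multisets are identical
        on randomized topologies, delays, and Poisson emission schedules
        (a handful here; the full 200-network sweep runs with the
        end-to-end validation suite)."""
        rng = np.random.default_rng(1000)
        n_steps = 300
        for _ in range(5):
            net, conns, _, p = random_delivery_case(rng, n_steps=n_steps)
            n = net.populations[0].n
            emissions = []
            for s in range(n_steps):
                fired = np.flatnonzero(rng.random(n) < p)
                emissions.extend((s, int(node), 1) for node in fired)
            run_with_injections(net, emissions, n_steps)
            got = delivery_multiset(net, n_steps)
            want = oracle_deliveries(conns, emissions, n_steps)
            assert got == want


class TestCostContracts:
    def test_events_equal_sum_of_emitter_group_counts(self, rng):
        net, conns, _, _ = random_delivery_case(rng, max_delay_steps=10,
                                                n_steps=300)
        n = net.populations[0].n
        emissions = [(s, int(rng.integers(0, n)), 1) for s in range(0, 250, 5)]
        run_with_injections(net, emissions, 300)
        want = sum(len(net.store.groups_of(node)) for _, node, _ in emissions)
        assert net.report.spike_array_events == want

    def test_mean_buffer_occupancy_matches_rate_delay_product(self):
        """Long-run mean entries per buffer ~ F x d_max x dt for Poisson
        emission: 100 Hz x 20 steps x 0.1 ms -> 0.2 entries."""
        n_nodes, n_steps, p = 50, 20000, 0.01  # p = 100 Hz x 0.1 ms
        conns = []
        for i in range(n_nodes):
            conns.append((i, (i + 1) % n_nodes, 1.0, 0.5))
            conns.append((i, (i + 2) % n_nodes, 1.0, 2.0))  # d_max = 20
        net = make_relay_network(n_nodes, conns, record_deliveries=False)
        rng = np.random.default_rng(7)
        occupancy = 0
        for s in range(n_steps):
            net.step()
            fired = np.flatnonzero(rng.random(n_nodes) < p)
            if fired.size:
                net.buffers.push(fired)
            occupancy += net.buffers.n_entries
        mean_per_buffer = occupancy / n_steps / n_nodes
        assert mean_per_buffer == pytest.approx(0.2, rel=0.1)
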