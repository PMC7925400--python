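"""Independent brute-force references used by the test suite.

Nothing here shares delivery or integration code with the main modules:

* :func:`oracle_deliveries` — a circular event queue that schedules every
  synaptic event individually at emission step + delay, with no grouping;
* :func:`reference_integrate` — classical fixed-step 4th-order Runge-Kutta
  at a fine stride, for checking the adaptive AdEx integrator and the
  two-substep Izhikevich update;
* :func:`oracle_simulate_adex` — a complete second backend for the AdEx
  balanced network (event-queue delivery + fixed-substep RK4 dynamics),
  used by the seed-compatibility protocol.

These references are exercised only on desk-scale instances.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

__all__ = ["oracle_deliveries", "reference_integrate",
           "oracle_simulate_adex", "adex_rhs"]


def oracle_deliveries(connections, emissions, n_steps):
    """Exhaustive per-connection event-queue delivery.

    ``connections``: iterable of (source, target, weight, delay_steps).
    ``emissions``: iterable of (step, node, multiplicity) — the step at
    which the node emitted (pushed) the spike.
    Returns a Counter over (source, target, delivery_step, amount) for all
    deliveries that fall within ``n_steps``.
    """
    adjacency = defaultdict(list)
    for src, tgt, w, d in connections:
        adjacency[int(src)].append((int(tgt), float(w), int(d)))
    queue = defaultdict(list)
    for step, node, mult in emissions:
        for tgt, w, d in adjacency[int(node)]:
            queue[int(step) + d].append((int(node), tgt, w * int(mult)))
    out = Counter()
    for step in sorted(queue):
        if step >= n_steps:
            continue
        for src, tgt, amount in queue[step]:
            out[(src, tgt, step, amount)] += 1
    return out


def _rk4(f, y, h):
    k1 = f(y)
    k2 = f(y + 0.5 * h * k1)
    k3 = f(y + 0.5 * h * k2)
    k4 = f(y + h * k3)
    return y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def reference_integrate(f, y0, t_end, fine_dt, record_every=1,
                        spike_detect=None, spike_reset=None):
    """Dense fixed-step RK4 trajectory of dy/dt = f(y).

    ``spike_detect(y) -> bool`` and ``spike_reset(y) -> y`` implement
    threshold handling (checked after every fine step).  Returns
    (times, trajectory, spike_times).  Threshold crossings are located by
    bisection on partial RK4 steps, so the reset time is resolved far below
    ``fine_dt``.
    """
    n_steps = int(round(t_end / fine_dt))
    y = np.array(y0, dtype=float)
    times, traj, spikes = [0.0], [y.copy()], []
    for i in range(n_steps):
        y_prev = y
        y = _rk4(f, y, fine_dt)
        t = (i + 1) * fine_dt
        if spike_detect is not None and spike_detect(y):
            lo, hi = 0.0, 1.0
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if spike_detect(_rk4(f, y_prev, mid * fine_dt)):
                    hi = mid
                else:
                    lo = mid
            y_cross = _rk4(f, y_prev, hi * fine_dt)
            spikes.append(i * fine_dt + hi * fine_dt)
            y = spike_reset(y_cross)
            rest = (1.0 - hi) * fine_dt
            if rest > 0:
                y = _rk4(f, y, rest)
        if (i + 1) % record_every == 0:
            times.append(t)
            traj.append(y.copy())
    return np.asarray(times), np.asarray(traj), np.asarray(spikes)


def adex_rhs(params):
    """Scalar-friendly AdEx + alpha-conductance right-hand side (own code)."""
    p = params

    def f(y):
        V, w = y[0], y[1]
        Vc = np.minimum(V, p["V_peak"])
        I_syn = 0.0
        n_ports = (len(y) - 2) // 2
        for i in range(n_ports):
            I_syn = I_syn + y[2 + 2 * i] * (V - p["E_rev"][i])
        exp_arg = np.minimum((Vc - p["V_T"]) / p["Delta_T"], 10.0)
        dV = (-p["g_L"] * (V - p["E_L"]) + p["g_L"] * p["Delta_T"]
              * np.exp(exp_arg)
              - I_syn + p["I_e"] - w) / p["C"]
        dw = (p["a"] * (V - p["E_L"]) - w) / p["tau_w"]
        out = [dV, dw]
        for i in range(n_ports):
            g, hh = y[2 + 2 * i], y[3 + 2 * i]
            out.append(hh - g / p["tau_decay"][i])
            out.append(-hh / p["tau_rise"][i])
        return np.asarray(out)

    return f


def oracle_simulate_adex(built, duration, seed, n_sub=10):
    """Independent backend for a built AdEx balanced network.

    Takes the calibrated connection tables of ``built`` (a
    :class:`~spikesim.model_zoo.BuiltNetwork`) as data, but runs its own
    loop: per-connection circular-queue delivery, per-target Poisson drive
    draws, and fixed-substep classical RK4 dynamics.  Returns
    (sender ids, spike times ms).
    """
    net = built.network
    net.calibrate()
    st = net.store
    dt = net.dt
    pops = [p for p in net.populations]
    n_neurons = sum(p.n for p in pops)
    params = pops[0].params
    n_ports = pops[0].n_ports
    alpha_norm = np.array([np.e / params["tau_decay"][i]
                           for i in range(n_ports)])

    # per-source adjacency from the calibrated (sorted) connection arrays
    order = np.argsort(st.source, kind="stable")
    src_sorted = st.source[order]
    starts = np.searchsorted(src_sorted, np.arange(net.n_nodes), "left")
    ends = np.searchsorted(src_sorted, np.arange(net.n_nodes), "right")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(99,)))
    gen = built.generators[0]
    lam = gen.rate * dt / 1000.0
    w_poisson = built.resolved["w_poisson"]

    y = np.zeros((2 + 2 * n_ports, n_neurons))
    y[0] = np.concatenate([p.y[0].copy() for p in pops])
    queue = defaultdict(list)
    rhs_params = params
    senders, times = [], []
    n_steps = int(round(duration / dt))
    h = dt / n_sub

    def deriv(yv):
        V, w = yv[0], yv[1]
        Vc = np.minimum(V, rhs_params["V_peak"])
        I_syn = 0.0
        for i in range(n_ports):
            I_syn = I_syn + yv[2 + 2 * i] * (V - rhs_params["E_rev"][i])
        exp_arg = np.minimum((Vc - rhs_params["V_T"])
                             / rhs_params["Delta_T"], 10.0)
        dV = (-rhs_params["g_L"] * (V - rhs_params["E_L"])
              + rhs_params["g_L"] * rhs_params["Delta_T"]
              * np.exp(exp_arg)
              - I_syn + rhs_params["I_e"] - w) / rhs_params["C"]
        dw = (rhs_params["a"] * (V - rhs_params["E_L"]) - w) \
            / rhs_params["tau_w"]
        out = np.empty_like(yv)
        out[0], out[1] = dV, dw
        for i in range(n_ports):
            out[2 + 2 * i] = yv[3 + 2 * i] - yv[2 + 2 * i] \
                / rhs_params["tau_decay"][i]
            out[3 + 2 * i] = -yv[3 + 2 * i] / rhs_params["tau_rise"][i]
        return out

    for s in range(n_steps):
        # deliveries scheduled for this step: per-connection events plus the
        # tagged Poisson drive packets
        amp = np.zeros((n_neurons, n_ports))
        for item in queue.pop(s, []):
            if isinstance(item, tuple) and item[0] == "poisson":
                amp[:, 0] += item[1]
            else:
                np.add.at(amp, (st.target[item], st.port[item]),
                          st.weight[item])
        # Poisson drive: independent per-target draws, one-step delay
        mult = rng.poisson(lam, size=n_neurons)
        queue[s + 1].append(("poisson", w_poisson * mult))

        for i in range(n_ports):
            y[3 + 2 * i] += amp[:, i] * alpha_norm[i]
        spiked = np.zeros(n_neurons, dtype=bool)
        for _ in range(n_sub):
            y = _rk4(deriv, y, h)
            crossed = y[0] >= rhs_params["V_peak"]
            if crossed.any():
                y[0, crossed] = rhs_params["V_r"]
                y[1, crossed] += rhs_params["b"]
                spiked |= crossed
        ids = np.flatnonzero(spiked)
        if ids.size:
            t_event = (s + 1) * dt
            senders.extend(ids.tolist())
            times.extend([t_event] * ids.size)
            for nid in ids:
                cids = order[starts[nid]:ends[nid]]
                if cids.size == 0:
                    continue
                for d in np.unique(st.delay_steps[cids]):
                    queue[s + int(d)].append(
                        cids[st.delay_steps[cids] == d])
    return np.asarray(senders, dtype=np.int64), np.asarray(times)
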