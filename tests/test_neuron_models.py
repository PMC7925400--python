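"""Neuron dynamics: LIF exactness, AdEx adaptive integration, Izhikevich."""

import numpy as np
import pytest

from spikesim.neuron_models import (ADEX_DEFAULTS, AdExPopulation,
                                    IzhikevichPopulation, LIFPopulation,
                                    adex_derivatives, beta_normalization,
                                    izhi_step, lif_step)
from spikesim.oracle import adex_rhs, reference_integrate


class TestLIF:
    def test_resting_fixed_point(self):
        st, spiked = lif_step(dict(V_m=-65.0, I_syn=0.0),
                              dict(E_L=-65.0), 0.1)
        assert st["V_m"] == -65.0 and st["I_syn"] == 0.0 and not spiked

    def test_single_step_closed_form(self):
        st, _ = lif_step(dict(V_m=-55.0, I_syn=0.0),
                         dict(E_L=-65.0, tau_m=10.0, V_th=0.0), 0.1)
        assert st["V_m"] == pytest.approx(-65.0 + 10.0 * np.exp(-0.01),
                                          abs=1e-12)

    def test_exact_against_analytic_arrival_sequence(self):
        """Exact propagation: max |V - analytic| < 1e-9 mV over 1e4 steps
        under an arbitrary fixed spike-arrival sequence."""
        dt, n_steps = 0.1, 10_000
        p = dict(tau_m=10.0, E_L=-65.0, R_m=0.04, tau_syn=0.5, V_th=1e9)
        rng = np.random.default_rng(5)
        arrival_steps = np.sort(rng.choice(n_steps, size=25, replace=False))
        weights = rng.uniform(-200, 400, size=25)
        pop = LIFPopulation(1, p)
        pop.calibrate(dt)
        arr = np.zeros((1, 1))
        vs = np.empty(n_steps)
        for s in range(n_steps):
            arr[0, 0] = weights[arrival_steps == s].sum()
            pop.update(arr, dt)
            vs[s] = pop.V_m[0]
        # analytic superposition of exponential PSC responses
        t = (np.arange(n_steps) + 1) * dt
        A = p["R_m"] * p["tau_syn"] / (p["tau_syn"] - p["tau_m"])
        v_ref = np.full(n_steps, p["E_L"])
        for s, w in zip(arrival_steps, weights):
            tau = t - s * dt
            mask = tau >= dt * 0.5
            v_ref[mask] += w * A * (np.exp(-tau[mask] / p["tau_syn"])
                                    - np.exp(-tau[mask] / p["tau_m"]))
        assert np.max(np.abs(vs - v_ref)) < 1e-9

    def test_degenerate_equal_time_constants_limit(self):
        dt = 0.1
        p = dict(tau_m=2.0, tau_syn=2.0, E_L=-65.0, R_m=0.05, V_th=1e9)
        pop = LIFPopulation(1, p)
        pop.calibrate(dt)
        pop.update(np.array([[100.0]]), dt)
        # V(dt) = E_L + w R (dt/tau) exp(-dt/tau)
        want = -65.0 + 100.0 * 0.05 * (dt / 2.0) * np.exp(-dt / 2.0)
        assert pop.V_m[0] == pytest.approx(want, abs=1e-12)

    def test_refractory_pins_voltage_while_current_evolves(self):
        p = dict(E_L=-65.0, V_th=-64.9, V_reset=-70.0, t_ref=1.0,
                 tau_syn=0.5)
        pop = LIFPopulation(1, p)
        pop.calibrate(0.1)
        spiked = pop.update(np.array([[5000.0]]), 0.1)
        assert spiked[0]
        i_after = pop.I_syn[0]
        for _ in range(5):
            pop.update(np.zeros((1, 1)), 0.1)
        assert pop.V_m[0] == -70.0
        assert 0 < pop.I_syn[0] < i_after


class TestAdExDerivatives:
    def test_near_fixed_point_at_rest(self):
        p = AdExPopulation(1).params
        y = np.zeros((6, 1))
        y[0] = p["E_L"]
        d = adex_derivatives(y, p)
        assert abs(d[0, 0]) < 1e-5  # residual exp term ~ gL DT e^-10.1 / C

    def test_pure_adaptation_decay_when_a_zero(self):
        pop = AdExPopulation(1, params={"a": 0.0})
        y = np.zeros((6, 1))
        y[0], y[1] = pop.params["E_L"], 100.0
        d = adex_derivatives(y, pop.params)
        assert d[1, 0] == pytest.approx(-100.0 / pop.params["tau_w"])

    def test_synaptic_current_drives_toward_reversal(self):
        pop = AdExPopulation(1)
        y = np.zeros((6, 1))
        y[0] = -70.6
        y[2] = 1.0  # 1 nS on the excitatory port, E_rev = 0
        d = adex_derivatives(y, pop.params)
        base = adex_derivatives(np.array([[-70.6, 0, 0, 0, 0, 0.]]).T,
                                pop.params)
        contrib = (d[0, 0] - base[0, 0]) * pop.params["C"]
        assert contrib == pytest.approx(70.6, rel=1e-12)  # pA, depolarizing

    def test_alpha_limit_of_beta_normalization(self):
        assert beta_normalization(1.0, 1.0) == pytest.approx(np.e)
        # general beta: unit weight peaks at exactly 1 nS
        c = beta_normalization(0.5, 2.0)
        tp = (0.5 * 2.0 / 1.5) * np.log(4.0)
        g_peak = c * (np.exp(-tp / 2.0) - np.exp(-tp / 0.5)) / (1 / 2 - 1 / .5)
        assert g_peak == pytest.approx(1.0)


class TestAdExIntegration:
    def test_quiescent_neuron_stays_at_rest(self):
        pop = AdExPopulation(1)
        pop.calibrate(0.1)
        arr = np.zeros((1, 2))
        for _ in range(1000):
            pop.update(arr, 0.1)
        assert abs(pop.V[0] - ADEX_DEFAULTS["E_L"]) < 1e-3

    def test_current_step_fires_with_growing_intervals(self):
        """700 pA step: repetitive firing with lengthening ISIs (adaptation),
        and the adaptation current jumps by exactly b at every spike."""
        pop = AdExPopulation(1, params={"I_e": 700.0})
        pop.calibrate(0.1)
        arr = np.zeros((1, 2))
        spikes, w_jumps = [], []
        for s in range(3000):
            w_before = pop.w[0]
            if pop.update(arr, 0.1)[0]:
                spikes.append((s + 1) * 0.1)
                w_jumps.append(pop.w[0] - w_before)
        assert len(spikes) >= 3
        isis = np.diff(spikes)
        assert np.all(np.diff(isis) > 0)
        # w increment = b + integration drift within the step (<< b)
        assert np.allclose(w_jumps, 80.5, atol=1.0)

    def test_subthreshold_step_matches_fine_reference(self):
        """Subthreshold response to a small current step agrees with a
        classical fixed-step 4th-order reference at a 1000x finer stride."""
        dt, t_end = 0.1, 20.0
        pop = AdExPopulation(1, params={"I_e": 200.0})
        pop.calibrate(dt)
        arr = np.zeros((1, 2))
        v_main = np.empty(int(t_end / dt))
        for s in range(v_main.size):
            pop.update(arr, dt)
            v_main[s] = pop.V[0]
        p = pop.params
        y0 = np.zeros(6)
        y0[0] = p["E_L"]
        _, traj, _ = reference_integrate(adex_rhs(p), y0, t_end,
                                         fine_dt=dt / 1000,
                                         record_every=1000)
        assert np.max(np.abs(v_main - traj[1:, 0])) < 1e-4

    def test_halving_tolerance_preserves_spike_steps(self):
        def spike_steps(tol):
            pop = AdExPopulation(1, params={"I_e": 700.0}, error_tol=tol)
            pop.calibrate(0.1)
            arr = np.zeros((1, 2))
            return [s for s in range(2000) if pop.update(arr, 0.1)[0]]

        a, b = spike_steps(1e-8), spike_steps(5e-9)
        assert len(a) == len(b)
        assert np.max(np.abs(np.array(a) - np.array(b))) <= 1


def _reset(y, p):
    y = y.copy()
    y[0] = p["V_r"]
    y[1] += p["b"]
    return y


class TestIzhikevich:
    def test_stationary_point(self):
        st, spiked = izhi_step(dict(v=-70.0, u=-14.0), None, 1.0)
        assert (st["v"], st["u"]) == (-70.0, -14.0) and not spiked

    def test_spike_reset_values(self):
        st, spiked = izhi_step(dict(v=29.9, u=0.0), None, 1.0,
                               arrivals=200.0)
        assert spiked and st["v"] == -65.0 and st["u"] == pytest.approx(8.0,
                                                                        abs=0.2)

    def test_tonic_firing_matches_fine_reference(self):
        """Two-substep Euler at dt=1 ms reproduces the spike count of a
        0.01 ms RK4 reference within one spike over 1 s, constant drive."""
        I = 10.0
        pop = IzhikevichPopulation(1, params={"I_e": I})
        pop.calibrate(1.0)
        arr = np.zeros((1, 1))
        n_main = sum(int(pop.update(arr, 1.0)[0]) for _ in range(1000))

        a, b, c, d = 0.02, 0.2, -65.0, 8.0

        def f(y):
            v, u = y
            return np.array([0.04 * v * v + 5 * v + 140 - u + I,
                             a * (b * v - u)])

        y0 = np.array([pop.v[0] * 0 - 70.0, -14.0])
        _, _, spikes = reference_integrate(
            f, y0, 1000.0, fine_dt=0.01, record_every=1000,
            spike_detect=lambda y: y[0] >= 30.0,
            spike_reset=lambda y: np.array([c, y[1] + d]))
        assert abs(n_main - len(spikes)) <= 1

    def test_synaptic_current_decays_exponentially(self):
        pop = IzhikevichPopulation(1)
        pop.calibrate(1.0)
        pop.update(np.array([[6.0]]), 1.0)
        assert pop.I_syn[0] == pytest.approx(6.0 * np.exp(-0.5))
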