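"""Neuron populations: LIF (exact integration), multisynapse AdEx (adaptive
fifth-order Runge-Kutta), and Izhikevich (forward Euler, two substeps).

Each population is a homogeneous array of states updated vectorized over one
network time step.  Input arrives as a per-step, per-receptor-port
accumulated amplitude: summed synaptic weight (pA) for current-based models,
summed peak conductance (nS) for the conductance-based AdEx ports.

LIF
    tau_m dV/dt = -(V - E_L) + R_m (I_syn + I_e)
    tau_syn dI_syn/dt = -I_syn + sum_j w_ij sum_f delta(t - t_j^f)
    Linear, so one-step propagation on the time grid is exact (no truncation
    error at any dt).  Threshold/reset with an absolute refractory clamp.

AdEx
    C dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T)
              - sum_i g_i(t) (V - E_rev_i) + I_e - w
    tau_w dw/dt = a (V - E_L) - w
    with beta-function synaptic conductances per receptor port
    (dg/dt = h - g/tau_decay, dh/dt = -h/tau_rise; alpha function in the
    tau_rise == tau_decay limit).  A spike at V >= V_peak resets V -> V_r and
    w -> w + b.  Integrated by the Cash-Karp embedded 4(5) pair with
    per-neuron adaptive internal step control.

Izhikevich
    dv/dt = 0.04 v^2 + 5 v + 140 - u + I ,  du/dt = a (b v - u)
    at dt = 1 ms with two 0.5 ms Euler substeps; exponential-decay
    current-based synapse; spike at v >= 30 mV resets v -> c, u -> u + d.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LIFPopulation", "AdExPopulation", "IzhikevichPopulation",
           "lif_step", "adex_derivatives", "izhi_step",
           "LIF_DEFAULTS", "ADEX_DEFAULTS", "IZHI_DEFAULTS",
           "beta_peak_time", "beta_normalization"]

# ---------------------------------------------------------------------------
# parameter defaults (AdEx values are the balanced-network set)

LIF_DEFAULTS = dict(tau_m=10.0, E_L=-65.0, R_m=0.04, tau_syn=0.5,
                    V_th=-50.0, V_reset=-65.0, t_ref=2.0, I_e=0.0)
# R_m in GOhm so that R_m * I[pA] is in mV

ADEX_DEFAULTS = dict(C=281.0, g_L=30.0, E_L=-70.6, V_T=-50.4, Delta_T=2.0,
                     tau_w=144.0, a=4.0, b=80.5, V_r=-60.0, V_peak=0.0,
                     I_e=0.0, t_ref=0.0,
                     E_rev=(0.0, -85.0), tau_rise=(1.0, 1.0),
                     tau_decay=(1.0, 1.0))

IZHI_DEFAULTS = dict(a=0.02, b=0.2, c=-65.0, d=8.0, tau_decay=2.0, I_e=0.0)


def beta_peak_time(tau_rise, tau_decay):
    """Time of the conductance peak after a single incoming spike."""
    if np.isclose(tau_rise, tau_decay):
        return tau_decay
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * np.log(tau_decay / tau_rise))


def beta_normalization(tau_rise, tau_decay):
    """Scale on the rise variable so a unit-weight spike peaks at 1 nS.

    The impulse response of (dh = -h/tau_r, dg = h - g/tau_d) to h(0) = h0 is
    g(t) = h0 (exp(-t/tau_r) - exp(-t/tau_d)) / (1/tau_d - 1/tau_r), an alpha
    function h0 t exp(-t/tau) in the equal-tau limit.  Returns 1/peak of the
    unit-h0 response.
    """
    if np.isclose(tau_rise, tau_decay):
        return np.e / tau_decay
    tp = beta_peak_time(tau_rise, tau_decay)
    g_unit = (np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)) \
        / (1.0 / tau_decay - 1.0 / tau_rise)
    return 1.0 / g_unit


class PopulationBase:
    model_tag = "base"
    n_ports = 1

    def __init__(self, n, first_id=0):
        self.n = int(n)
        self.first_id = int(first_id)

    @property
    def ids(self):
        return np.arange(self.first_id, self.first_id + self.n)

    def calibrate(self, dt):  # pragma: no cover - overridden where needed
        pass

    def get_state(self, name):
        raise KeyError(name)


# ---------------------------------------------------------------------------
# LIF

class LIFPopulation(PopulationBase):
    """Current-based LIF neurons advanced by the exact propagator."""

    model_tag = "lif_psc_exp"
    n_ports = 1

    def __init__(self, n, params=None, first_id=0):
        super().__init__(n, first_id)
        p = dict(LIF_DEFAULTS)
        p.update(params or {})
        for k, v in p.items():
            setattr(self, k, np.broadcast_to(np.asarray(v, float), (self.n,)).copy()
                    if np.ndim(v) else float(v))
        self.V_m = np.full(n, float(np.mean(p["E_L"])))
        self.I_syn = np.zeros(n)
        self.ref_left = np.zeros(n, dtype=np.int64)

    def set_initial_potential(self, V0):
        self.V_m[:] = V0

    def calibrate(self, dt):
        self.dt = dt
        tau_m = np.asarray(self.tau_m, float)
        tau_s = np.asarray(self.tau_syn, float)
        self._p_mem = np.exp(-dt / tau_m)
        self._p_syn = np.exp(-dt / tau_s)
        same = np.isclose(tau_m, tau_s)
        with np.errstate(divide="ignore", invalid="ignore"):
            gen = (np.asarray(self.R_m) * tau_s / (tau_s - tau_m)
                   * (self._p_syn - self._p_mem))
        lim = np.asarray(self.R_m) * dt * self._p_mem / tau_m
        self._prop = np.where(same, lim, gen)
        self._ref_steps = np.maximum(
            np.rint(np.asarray(self.t_ref, float) / dt), 0).astype(np.int64)

    def update(self, arrivals, dt):
        I = self.I_syn + arrivals[:, 0]
        V_inf = self.E_L + np.asarray(self.R_m) * np.asarray(self.I_e)
        V_new = V_inf + (self.V_m - V_inf) * self._p_mem + I * self._prop
        refr = self.ref_left > 0
        self.V_m = np.where(refr, self.V_reset, V_new)
        self.I_syn = I * self._p_syn
        self.ref_left[refr] -= 1
        spiked = (~refr) & (self.V_m >= self.V_th)
        if spiked.any():
            self.V_m[spiked] = np.broadcast_to(
                np.asarray(self.V_reset, float), (self.n,))[spiked]
            self.ref_left[spiked] = np.broadcast_to(
                self._ref_steps, (self.n,))[spiked]
        return spiked

    def get_state(self, name):
        return {"V_m": self.V_m, "I_syn": self.I_syn}[name]


def lif_step(state, params, dt, arrivals=0.0):
    """Single-neuron convenience wrapper around the exact LIF propagator.

    ``state`` is a dict with V_m, I_syn, ref_left; returns (new_state, spiked).
    """
    pop = LIFPopulation(1, params)
    pop.V_m[:] = state["V_m"]
    pop.I_syn[:] = state["I_syn"]
    pop.ref_left[:] = state.get("ref_left", 0)
    pop.calibrate(dt)
    spiked = pop.update(np.array([[arrivals]]), dt)
    return (dict(V_m=float(pop.V_m[0]), I_syn=float(pop.I_syn[0]),
                 ref_left=int(pop.ref_left[0])), bool(spiked[0]))


# ---------------------------------------------------------------------------
# AdEx with Cash-Karp 4(5)

_CK_A = (0.0, 0.2, 0.3, 0.6, 1.0, 0.875)
_CK_B = (
    (),
    (1 / 5,),
    (3 / 40, 9 / 40),
    (3 / 10, -9 / 10, 6 / 5),
    (-11 / 54, 5 / 2, -70 / 27, 35 / 27),
    (1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096),
)
_CK_C5 = (37 / 378, 0.0, 250 / 621, 125 / 594, 0.0, 512 / 1771)
_CK_C4 = (2825 / 27648, 0.0, 18575 / 48384, 13525 / 55296, 277 / 14336, 1 / 4)
_CK_DC = tuple(c5 - c4 for c5, c4 in zip(_CK_C5, _CK_C4))

_SAFETY = 0.9
_GROW_EXP = -0.2
_SHRINK_EXP = -0.25
_MAX_GROW = 5.0
_MIN_SHRINK = 0.1
_H_MIN = 1e-10  # ms; below this the controller reports step-size underflow


MAX_EXP_ARG = 10.0  # cap on (V - V_T)/Delta_T in the spike-initiation term


def adex_derivatives(y, params):
    """Right-hand side of the AdEx + beta-synapse ODE system.

    ``y`` has rows [V, w, g_0, h_0, g_1, h_1, ...] and any number of columns.
    The argument of the exponential spike-initiation term is clamped (at
    V_peak and at ``MAX_EXP_ARG``): above threshold the trajectory is in
    runaway toward the spike ceiling anyway, and the cap keeps the system
    integrable during the crossing substep without affecting grid-resolution
    spike times.
    """
    p = params
    V, w = y[0], y[1]
    Vc = np.minimum(V, p["V_peak"])
    I_syn = 0.0
    n_ports = (y.shape[0] - 2) // 2
    for i in range(n_ports):
        g = y[2 + 2 * i]
        I_syn = I_syn + g * (V - p["E_rev"][i])
    exp_arg = np.minimum((Vc - p["V_T"]) / p["Delta_T"], MAX_EXP_ARG)
    dV = (-p["g_L"] * (V - p["E_L"])
          + p["g_L"] * p["Delta_T"] * np.exp(exp_arg)
          - I_syn + p["I_e"] - w) / p["C"]
    dw = (p["a"] * (V - p["E_L"]) - w) / p["tau_w"]
    out = np.empty_like(y)
    out[0], out[1] = dV, dw
    for i in range(n_ports):
        g, h = y[2 + 2 * i], y[3 + 2 * i]
        out[2 + 2 * i] = h - g / p["tau_decay"][i]
        out[3 + 2 * i] = -h / p["tau_rise"][i]
    return out


def _hermite_crossing(y0, y1, k0, k1, hc, v_peak, iters=40):
    """Locate the V = v_peak crossing inside one RK substep.

    Uses the cubic Hermite dense-output interpolant through the substep's
    endpoint values and derivatives.  Returns (theta, state at crossing)
    with theta in (0, 1]; bisection on the V component of the cubic.
    """
    def basis(theta):
        t2 = theta * theta
        h00 = 2 * t2 * theta - 3 * t2 + 1
        h10 = t2 * theta - 2 * t2 + theta
        h01 = -2 * t2 * theta + 3 * t2
        h11 = t2 * theta - t2
        return h00, h10, h01, h11

    v0, v1 = y0[0], y1[0]
    dv0, dv1 = hc * k0[0], hc * k1[0]
    lo = np.zeros(hc.shape)
    hi = np.ones(hc.shape)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        h00, h10, h01, h11 = basis(mid)
        above = h00 * v0 + h10 * dv0 + h01 * v1 + h11 * dv1 >= v_peak
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    theta = hi
    h00, h10, h01, h11 = basis(theta)
    y_cross = h00 * y0 + h10 * hc * k0 + h01 * y1 + h11 * hc * k1
    return theta, y_cross


class AdExPopulation(PopulationBase):
    """Multisynapse AdEx neurons with conductance-based beta/alpha receptors.

    ``error_tol`` is the dimensionless accuracy demanded of every adaptive
    substep (error scaled by |y| + |h y'|).
    """

    model_tag = "aeif_cond_beta"

    def __init__(self, n, params=None, n_receptors=2, first_id=0,
                 error_tol=1e-8, spike_handling="resolve"):
        if spike_handling not in ("resolve", "fast"):
            raise ValueError("spike_handling must be 'resolve' or 'fast'")
        self.spike_handling = spike_handling
        super().__init__(n, first_id)
        p = dict(ADEX_DEFAULTS)
        if params:
            p.update(params)
        for key in ("E_rev", "tau_rise", "tau_decay"):
            v = np.atleast_1d(np.asarray(p[key], float))
            if v.size == 1:
                v = np.repeat(v, n_receptors)
            if v.size != n_receptors:
                raise ValueError(f"{key} must have one value per receptor")
            p[key] = v
        if np.any(p["tau_rise"] > p["tau_decay"]):
            raise ValueError("tau_rise must not exceed tau_decay")
        if p["Delta_T"] <= 0:
            raise ValueError("Delta_T must be positive")
        self.params = p
        self.n_ports = int(n_receptors)
        self.error_tol = float(error_tol)
        self.y = np.zeros((2 + 2 * self.n_ports, n))
        self.y[0] = p["E_L"]
        self.c_norm = np.array([beta_normalization(p["tau_rise"][i],
                                                   p["tau_decay"][i])
                                for i in range(self.n_ports)])
        self.ref_left = np.zeros(n, dtype=np.int64)
        self._h_last = None

    # state accessors -------------------------------------------------
    @property
    def V(self):
        return self.y[0]

    @property
    def w(self):
        return self.y[1]

    def get_state(self, name):
        if name == "V_m":
            return self.y[0]
        if name == "w":
            return self.y[1]
        if name.startswith("g_"):
            return self.y[2 + 2 * int(name[2:])]
        raise KeyError(name)

    def calibrate(self, dt):
        self.dt = dt
        p = self.params
        self._ref_steps = int(round(p["t_ref"] / dt))
        # onset voltage for 'fast' spike handling: above it the exponential
        # term slope exceeds 2 mV/ms and the membrane-voltage component is
        # exempted from step-size control (the upswing shape is not needed,
        # and V is still integrated, just not error-limited)
        self._v_commit = p["V_T"] + p["Delta_T"] * np.log(
            2.0 * p["C"] / (p["g_L"] * p["Delta_T"]))
        if self._h_last is None:
            self._h_last = np.full(self.n, dt)

    def update(self, arrivals, dt):
        p = self.params
        for i in range(self.n_ports):
            self.y[3 + 2 * i] += arrivals[:, i] * self.c_norm[i]
        spiked = np.zeros(self.n, dtype=bool)

        t = np.zeros(self.n)
        h = np.minimum(self._h_last, dt)
        active = np.full(self.n, True)
        guard = 0
        while active.any():
            guard += 1
            if guard > 10000:  # pragma: no cover
                raise RuntimeError("adaptive step-size control failed to "
                                   "complete a network time step")
            cols = np.flatnonzero(active)
            hc = np.minimum(h[cols], dt - t[cols])
            y0 = self.y[:, cols]
            k = []
            for s in range(6):
                ys = y0
                if s:
                    acc = _CK_B[s][0] * k[0]
                    for j in range(1, s):
                        if _CK_B[s][j] != 0.0:
                            acc = acc + _CK_B[s][j] * k[j]
                    ys = y0 + hc * acc
                k.append(adex_derivatives(ys, p))
            y5 = y0 + hc * (_CK_C5[0] * k[0] + _CK_C5[2] * k[2]
                            + _CK_C5[3] * k[3] + _CK_C5[5] * k[5])
            err = hc * (_CK_DC[0] * k[0] + _CK_DC[2] * k[2]
                        + _CK_DC[3] * k[3] + _CK_DC[4] * k[4]
                        + _CK_DC[5] * k[5])
            # |y| + |h y'| relative scale with a one-unit absolute floor so
            # variables resting at zero (w, g, h) are controlled absolutely
            scale = np.abs(y0) + np.abs(hc * k[0]) + 1.0
            err_scaled = np.abs(err) / scale
            errmax = np.max(err_scaled, axis=0) / self.error_tol
            if self.spike_handling == "fast":
                # once committed to a spike, the membrane-voltage component
                # is exempted from error control: the upswing shape is not
                # resolved, only the (grid-quantized) crossing matters
                committed = y0[0] > self._v_commit
                if committed.any():
                    # V and the V-coupled adaptation current are exempted;
                    # the decoupled synaptic conductances stay controlled
                    errmax_nov = np.max(err_scaled[2:], axis=0) \
                        / self.error_tol
                    errmax = np.where(committed, errmax_nov, errmax)
            accept = errmax <= 1.0
            crossing = accept & (y5[0] >= p["V_peak"])

            acc_cols = cols[accept]
            if acc_cols.size:
                sub = accept & ~crossing
                if sub.any():
                    scols = cols[sub]
                    self.y[:, scols] = y5[:, sub]
                    t[scols] += hc[sub]
                if crossing.any():
                    ccols = cols[crossing]
                    theta, y_cross = _hermite_crossing(
                        y0[:, crossing], y5[:, crossing],
                        k[0][:, crossing],
                        adex_derivatives(y5[:, crossing], p),
                        hc[crossing], p["V_peak"])
                    y_cross[0] = p["V_r"]
                    y_cross[1] += p["b"]
                    self.y[:, ccols] = y_cross
                    t[ccols] += theta * hc[crossing]
                    spiked[ccols] = True
                    if self._ref_steps > 0:
                        self.ref_left[ccols] = self._ref_steps
                e = np.maximum(errmax[accept], 1e-30)
                h[acc_cols] = np.minimum(hc[accept] * np.clip(
                    _SAFETY * e ** _GROW_EXP, _MIN_SHRINK, _MAX_GROW),
                    10 * dt)
            rej_cols = cols[~accept]
            if rej_cols.size:
                e = errmax[~accept]
                h_new = hc[~accept] * np.maximum(
                    _SAFETY * e ** _SHRINK_EXP, _MIN_SHRINK)
                if np.any(h_new < _H_MIN):
                    raise FloatingPointError(
                        "RK step-size underflow; state: "
                        f"{self.y[:, rej_cols[:5]]!r}")
                h[rej_cols] = h_new
            active[acc_cols] = t[acc_cols] < dt * (1 - 1e-12)

        if self._ref_steps > 0:
            refr = self.ref_left > 0
            if refr.any():
                self.y[0, refr] = p["V_r"]
                self.ref_left[refr] -= 1
                spiked &= ~refr
        self._h_last = h
        return spiked


# ---------------------------------------------------------------------------
# Izhikevich

def izhi_derivatives(v, u, I, a, b):
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I
    du = a * (b * v - u)
    return dv, du


class IzhikevichPopulation(PopulationBase):
    """Four-parameter Izhikevich neurons with exponential-decay current synapses."""

    model_tag = "izhikevich"
    n_ports = 1
    N_SUBSTEPS = 2

    def __init__(self, n, params=None, first_id=0):
        super().__init__(n, first_id)
        p = dict(IZHI_DEFAULTS)
        p.update(params or {})
        self.params = p
        b = p["b"]
        # start at the I=0 rest point: 0.04 v^2 + 5v + 140 = u = b v
        disc = (5.0 - b) ** 2 - 4 * 0.04 * 140.0
        v0 = (-(5.0 - b) - np.sqrt(disc)) / (2 * 0.04)
        self.v = np.full(n, v0)
        self.u = b * self.v
        self.I_syn = np.zeros(n)

    def calibrate(self, dt):
        self.dt = dt
        self._decay = np.exp(-dt / self.params["tau_decay"])

    def update(self, arrivals, dt):
        p = self.params
        self.I_syn += arrivals[:, 0]
        I = self.I_syn + p["I_e"]
        h = dt / self.N_SUBSTEPS
        spiked = np.zeros(self.n, dtype=bool)
        for _ in range(self.N_SUBSTEPS):
            live = ~spiked
            dv, du = izhi_derivatives(self.v, self.u, I, p["a"], p["b"])
            self.v = np.where(live, self.v + h * dv, self.v)
            self.u = np.where(live, self.u + h * du, self.u)
            crossed = live & (self.v >= 30.0)
            if crossed.any():
                self.v[crossed] = p["c"]
                self.u[crossed] += p["d"]
                spiked |= crossed
        self.I_syn *= self._decay
        return spiked

    def get_state(self, name):
        return {"V_m": self.v, "v": self.v, "u": self.u,
                "I_syn": self.I_syn}[name]


def izhi_step(state, params, dt=1.0, arrivals=0.0):
    """Single-neuron Izhikevich step; mirrors the population update."""
    pop = IzhikevichPopulation(1, params)
    pop.v[:] = state["v"]
    pop.u[:] = state["u"]
    pop.I_syn[:] = state.get("I_syn", 0.0)
    pop.calibrate(dt)
    spiked = pop.update(np.array([[arrivals]]), dt)
    return (dict(v=float(pop.v[0]), u=float(pop.u[0]),
                 I_syn=float(pop.I_syn[0])), bool(spiked[0]))
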