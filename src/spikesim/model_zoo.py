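"""Builders for the three benchmark networks.

* :func:`build_balanced_adex` — sparsely connected excitatory/inhibitory
  balanced network of conductance-based AdEx neurons driven by an external
  Poisson signal (20,000 Hz, weight 0.37 nS by default).  With the default
  parameters the population settles into asynchronous-irregular firing at a
  mean rate of roughly 30 Hz, independent of network size at fixed indegree.
* :func:`build_balanced_izhi` — same architecture with Izhikevich neurons,
  current-based exponential-decay synapses at dt = 1 ms, and nearest-neighbor
  STDP on the excitatory connections (inhibitory weights stay fixed).
* :func:`build_microcircuit` — the Potjans-Diesmann 1 mm^2 cortical
  microcircuit (eight LIF populations, ~77,000 neurons at full scale) at a
  configurable linear scale factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import microcircuit_constants as mc
from .connect import ConnSpec, SynSpec
from .kernel import Network
from .plasticity import STDPParams

__all__ = ["BalancedNetSpec", "MicrocircuitSpec", "BuiltNetwork",
           "build_balanced_adex", "build_balanced_izhi",
           "build_microcircuit"]


@dataclass
class BalancedNetSpec:
    """Parameters of the excitatory/inhibitory balanced network.

    Weights are peak conductances (nS) for the AdEx variant and current
    amplitudes (pA) for the Izhikevich variant.
    """

    n_ex: int = 10000
    ce: int = 1000
    w_ex: float = 0.05
    w_in: float = 0.35
    delay_mean: float = 0.5       # ms
    delay_std: float = 0.25       # ms
    w_poisson: float = 0.37
    rate_poisson: float = 20000.0  # Hz
    dt: float = 0.1               # ms
    seed: int = 12345
    neuron_params: Optional[dict] = None
    # network-level accuracy demand of the adaptive integrator; looser than
    # the single-neuron default because population statistics are insensitive
    # at this scale while the cost is ~2x
    error_tol: float = 1e-6

    @property
    def n_in(self):
        return self.n_ex // 4

    @property
    def ci(self):
        return self.ce // 4


@dataclass
class MicrocircuitSpec:
    """Potjans-Diesmann microcircuit at a linear scale factor in (0, 1]."""

    scale: float = 1.0
    dt: float = 0.1
    seed: int = 12345
    bg_rate: float = mc.BG_RATE_HZ
    # external indegrees are kept at full scale regardless of `scale` so the
    # downscaled network stays active (plain proportional scaling applies to
    # the recurrent synapse counts only)
    scale_external: bool = False

    def population_sizes(self):
        return np.rint(self.scale * mc.FULL_SIZES).astype(int)


@dataclass
class BuiltNetwork:
    """A constructed network plus handles to its parts and resolved spec."""

    network: Network
    populations: dict
    generators: list = field(default_factory=list)
    resolved: dict = field(default_factory=dict)


def _check_quarter(n_ex):
    if n_ex % 4:
        warnings.warn("n_ex not divisible by 4; inhibitory size rounded down")


def build_balanced_adex(spec: BalancedNetSpec = None, **overrides):
    """Build the AdEx balanced network (fixed indegree CE + CE/4)."""
    spec = spec or BalancedNetSpec()
    for k, v in overrides.items():
        setattr(spec, k, v)
    _check_quarter(spec.n_ex)
    net = Network(dt=spec.dt, seed=spec.seed)
    params = dict(spec.neuron_params or {})
    exc = net.create("aeif_cond_beta", spec.n_ex, params=params,
                     n_receptors=2, error_tol=spec.error_tol,
                     spike_handling="fast")
    inh = net.create("aeif_cond_beta", spec.n_in, params=params,
                     n_receptors=2, error_tol=spec.error_tol,
                     spike_handling="fast")
    all_ids = np.concatenate((exc.ids, inh.ids))

    # desynchronize the start: uniform V in [E_L, V_T]
    lo, hi = exc.params["E_L"], exc.params["V_T"]
    for pop in (exc, inh):
        pop.y[0] = net.init_rng.uniform(lo, hi, size=pop.n)

    delay = {"distribution": "normal",
             "mean": spec.delay_mean, "std": spec.delay_std}
    net.connect(exc, all_ids,
                ConnSpec(rule="fixed_indegree", indegree=spec.ce),
                SynSpec(weight=spec.w_ex, delay=delay, receptor=0))
    net.connect(inh, all_ids,
                ConnSpec(rule="fixed_indegree", indegree=spec.ci),
                SynSpec(weight=spec.w_in, delay=delay, receptor=1))
    gen = net.create_poisson_generator(spec.rate_poisson, independent=True)
    net.connect(gen, all_ids, ConnSpec(rule="all_to_all"),
                SynSpec(weight=spec.w_poisson, delay=spec.dt, receptor=0))
    resolved = dict(model="balanced_adex", n_ex=spec.n_ex, n_in=spec.n_in,
                    ce=spec.ce, ci=spec.ci, w_ex=spec.w_ex, w_in=spec.w_in,
                    delay_mean=spec.delay_mean, delay_std=spec.delay_std,
                    w_poisson=spec.w_poisson, rate_poisson=spec.rate_poisson,
                    dt=spec.dt, seed=spec.seed)
    return BuiltNetwork(net, {"exc": exc, "inh": inh}, [gen], resolved)


def build_balanced_izhi(poisson_rate, poisson_weight,
                        spec: BalancedNetSpec = None, stdp: STDPParams = None,
                        **overrides):
    """Build the Izhikevich balanced network with STDP excitatory synapses.

    Every neuron receives CE excitatory (plastic) and CE/4 inhibitory
    (static) inputs — 100 per neuron at the default CE = 80.  The external
    drive is not part of the published parameter set, so its rate (Hz) and
    weight (pA) are required arguments.
    """
    spec = spec or BalancedNetSpec(n_ex=8000, ce=80, w_ex=1.0, w_in=-8.0,
                                   delay_mean=1.0, delay_std=0.0, dt=1.0)
    for k, v in overrides.items():
        setattr(spec, k, v)
    stdp = stdp or STDPParams()
    _check_quarter(spec.n_ex)
    net = Network(dt=spec.dt, seed=spec.seed)
    exc = net.create("izhikevich", spec.n_ex)
    inh = net.create("izhikevich", spec.n_in)
    all_ids = np.concatenate((exc.ids, inh.ids))
    delay = spec.delay_mean if spec.delay_std == 0 else {
        "distribution": "normal", "mean": spec.delay_mean,
        "std": spec.delay_std}
    net.connect(exc, all_ids,
                ConnSpec(rule="fixed_indegree", indegree=spec.ce),
                SynSpec(weight=spec.w_ex, delay=delay,
                        synapse="stdp", stdp_params=stdp))
    net.connect(inh, all_ids,
                ConnSpec(rule="fixed_indegree", indegree=spec.ci),
                SynSpec(weight=spec.w_in, delay=delay))
    gen = net.create_poisson_generator(poisson_rate, independent=True)
    net.connect(gen, all_ids, ConnSpec(rule="all_to_all"),
                SynSpec(weight=poisson_weight, delay=spec.dt))
    resolved = dict(model="balanced_izhi", n_ex=spec.n_ex, n_in=spec.n_in,
                    ce=spec.ce, ci=spec.ci, w_ex=spec.w_ex, w_in=spec.w_in,
                    poisson_rate=poisson_rate, poisson_weight=poisson_weight,
                    dt=spec.dt, seed=spec.seed,
                    stdp=vars(stdp).copy())
    return BuiltNetwork(net, {"exc": exc, "inh": inh}, [gen], resolved)


def build_microcircuit(spec: MicrocircuitSpec = None, scale=None, **overrides):
    """Build the eight-population cortical microcircuit at a given scale.

    Recurrent pathway synapse counts are re-derived from the connection
    probability matrix at the scaled population sizes and realized with the
    fixed-total-number rule; the per-neuron external Poisson indegree stays
    at full scale (see module docs) unless ``scale_external`` is set.
    """
    spec = spec or MicrocircuitSpec()
    if scale is not None:
        spec.scale = scale
    for k, v in overrides.items():
        setattr(spec, k, v)
    if spec.scale <= 0:
        raise ValueError("scale must be positive")
    sizes = spec.population_sizes()
    net = Network(dt=spec.dt, seed=spec.seed)
    pops = {}
    for name, n in zip(mc.POPULATIONS, sizes):
        pop = net.create("lif_psc_exp", int(n), params=dict(mc.LIF_PARAMS))
        pop.set_initial_potential(
            net.init_rng.normal(mc.V0_MEAN, mc.V0_SD, size=pop.n))
        pops[name] = pop

    d_exc = {"distribution": "normal", "mean": mc.DELAY_EXC_MEAN,
             "std": mc.DELAY_EXC_MEAN * mc.DELAY_REL_SD}
    d_inh = {"distribution": "normal", "mean": mc.DELAY_INH_MEAN,
             "std": mc.DELAY_INH_MEAN * mc.DELAY_REL_SD}
    n_syn_total = 0
    for ti, tname in enumerate(mc.POPULATIONS):
        for si, sname in enumerate(mc.POPULATIONS):
            k = mc.pathway_synapse_number(mc.CONN_PROBS[ti, si],
                                          int(sizes[si]), int(sizes[ti]))
            if k == 0:
                continue
            n_syn_total += k
            if sname.endswith("E"):
                mean_w = (mc.W_L4E_TO_L23E_PA
                          if (sname == "4E" and tname == "2/3E")
                          else mc.W_EXC_PA)
                syn = SynSpec(weight={"distribution": "normal",
                                      "mean": mean_w,
                                      "std": 0.1 * mean_w, "min": 0.0},
                              delay=d_exc)
            else:
                syn = SynSpec(weight={"distribution": "normal",
                                      "mean": mc.W_INH_PA,
                                      "std": 0.1 * abs(mc.W_INH_PA),
                                      "max": 0.0},
                              delay=d_inh)
            net.connect(pops[sname], pops[tname],
                        ConnSpec(rule="fixed_total_number", total_number=k),
                        syn)

    gens = []
    ext_scale = spec.scale if spec.scale_external else 1.0
    for name, k_ext in zip(mc.POPULATIONS, mc.K_EXT):
        rate = ext_scale * k_ext * spec.bg_rate
        gen = net.create_poisson_generator(rate, independent=True)
        net.connect(gen, pops[name], ConnSpec(rule="all_to_all"),
                    SynSpec(weight=mc.W_EXC_PA, delay=mc.DELAY_EXC_MEAN))
        gens.append(gen)

    resolved = dict(model="microcircuit", scale=spec.scale,
                    sizes={n: int(s) for n, s in
                           zip(mc.POPULATIONS, sizes)},
                    n_recurrent_synapses=n_syn_total, dt=spec.dt,
                    seed=spec.seed, bg_rate=spec.bg_rate,
                    scale_external=spec.scale_external)
    return BuiltNetwork(net, pops, gens, resolved)
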