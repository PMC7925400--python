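"""Symmetric nearest-neighbor spike-timing-dependent plasticity.

Each synapse pairs an incoming (presynaptic) spike arrival only with the most
recent postsynaptic effect, and a postsynaptic effect only with the most
recent presynaptic arrival — the symmetric nearest-neighbor pairing scheme.
The weight change for a pairing with time difference dt = t_post - t_pre is

    dw = +lambda * w_max * (1 - w/w_max)**mu_plus * exp(-dt/tau_plus)   dt > 0
    dw = -lambda * alpha * w_max * (w/w_max)**mu_minus * exp(dt/tau_minus)  dt < 0

with no change at dt == 0.  mu = 0 gives the additive rule, mu = 1 the
multiplicative one.  Weights are clipped into [0, w_max] after every update.

Timing: the presynaptic side of a pairing uses the arrival time at the
synapse (emission time plus the axonal delay, which is identified with the
connection delay served by the spike buffer); the postsynaptic side uses the
spike time plus the dendritic backpropagation delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["STDPParams", "stdp_delta_w", "apply_pre_arrival", "apply_post_spike"]


@dataclass
class STDPParams:
    tau_plus: float = 20.0    # ms
    tau_minus: float = 20.0   # ms
    lambda_: float = 0.001    # learning rate
    alpha: float = 1.0        # depression/potentiation asymmetry
    mu_plus: float = 1.0      # weight-dependence exponent, potentiation
    mu_minus: float = 1.0     # weight-dependence exponent, depression
    w_max: float = 10.0       # weight ceiling

    def __post_init__(self):
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        if self.mu_plus < 0 or self.mu_minus < 0:
            raise ValueError("weight-dependence exponents must be >= 0")


def stdp_delta_w(w, dt_pair, p: STDPParams):
    """Closed-form weight change for a single pre/post pairing.

    Vectorized over ``w`` and ``dt_pair`` (ms).  The caller is responsible
    for clipping ``w + dw`` into [0, w_max].
    """
    w = np.asarray(w, dtype=float)
    dt_pair = np.asarray(dt_pair, dtype=float)
    wn = np.clip(w / p.w_max, 0.0, 1.0)
    pot = p.lambda_ * p.w_max * (1.0 - wn) ** p.mu_plus \
        * np.exp(-dt_pair / p.tau_plus)
    dep = -p.lambda_ * p.alpha * p.w_max * wn ** p.mu_minus \
        * np.exp(dt_pair / p.tau_minus)
    out = np.where(dt_pair > 0, pot, np.where(dt_pair < 0, dep, 0.0))
    if out.ndim == 0:
        return float(out)
    return out


def _updated(w, dt_pair, p):
    return np.clip(w + stdp_delta_w(w, dt_pair, p), 0.0, p.w_max)


def apply_pre_arrival(weights, conn_ids, t_now, targets, last_pre,
                      last_post_effect, param_sets, param_ids):
    """Presynaptic-side processing for a batch of delivered plastic synapses.

    For every connection whose postsynaptic neuron has already produced an
    effect, apply the depression branch with dt = last_post_effect - t_now
    (<= 0), then record ``t_now`` as the synapse's last presynaptic arrival.
    A multiplicity-m arrival counts as a single pairing event.
    """
    if conn_ids.size == 0:
        return
    lp = last_post_effect[targets]
    have_post = ~np.isnan(lp)
    if have_post.any():
        ids = conn_ids[have_post]
        dt_pair = lp[have_post] - t_now
        for pid in np.unique(param_ids[ids]):
            sel = ids[param_ids[ids] == pid]
            dsel = dt_pair[param_ids[ids] == pid]
            weights[sel] = _updated(weights[sel], dsel, param_sets[pid])
    last_pre[conn_ids] = t_now


def apply_post_spike(weights, incoming_ids, t_eff, last_pre,
                     param_sets, param_ids):
    """Postsynaptic-side processing for the plastic synapses of one or more
    neurons whose spike effect occurs at time ``t_eff``.

    Applies the potentiation branch with dt = t_eff - last_pre (> 0) for
    synapses that have seen a presynaptic arrival.  The caller updates the
    per-neuron last_post_effect bookkeeping afterwards.
    """
    if incoming_ids.size == 0:
        return
    lp = last_pre[incoming_ids]
    have_pre = ~np.isnan(lp)
    if not have_pre.any():
        return
    ids = incoming_ids[have_pre]
    dt_pair = t_eff - lp[have_pre]
    for pid in np.unique(param_ids[ids]):
        sel = ids[param_ids[ids] == pid]
        dsel = dt_pair[param_ids[ids] == pid]
        weights[sel] = _updated(weights[sel], dsel, param_sets[pid])
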