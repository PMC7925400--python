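"""Vendored parameters of the Potjans-Diesmann (2014) cortical microcircuit.

Source: Potjans & Diesmann (2014), "The cell-type specific cortical
microcircuit: relating structure and activity in a full-scale spiking
network model", Cerebral Cortex 24:785-806, as distributed with the NEST
microcircuit example implementation.  The model describes 1 mm^2 of sensory
cortex with four layers (2/3, 4, 5, 6), each split into an excitatory and an
inhibitory LIF population.
"""

from __future__ import annotations

import numpy as np

POPULATIONS = ("2/3E", "2/3I", "4E", "4I", "5E", "5I", "6E", "6I")

# full-scale population sizes (total 77,169 neurons)
FULL_SIZES = np.array([20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948])

# connection probabilities; row = target population, column = source population
CONN_PROBS = np.array([
    [0.1009, 0.1689, 0.0437, 0.0818, 0.0323, 0.0,    0.0076, 0.0],
    [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0,    0.0042, 0.0],
    [0.0077, 0.0059, 0.0497, 0.135,  0.0067, 0.0003, 0.0453, 0.0],
    [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0,    0.1057, 0.0],
    [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0],
    [0.0548, 0.0269, 0.0257, 0.0022, 0.06,   0.3158, 0.0086, 0.0],
    [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252],
    [0.0364, 0.001,  0.0034, 0.0005, 0.0277, 0.008,  0.0658, 0.1443],
])

# external (background) Poisson input: indegree per neuron and rate per input
K_EXT = np.array([1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100])
BG_RATE_HZ = 8.0

# synapse strengths as somatic PSP amplitudes (mV); converted to exponential
# PSC amplitudes (pA) below.  Inhibitory weights are -G_REL times excitatory;
# the L4E -> L2/3E pathway is doubled.
PSP_MEAN_MV = 0.15
PSP_REL_SD = 0.1
G_REL = 4.0
PSP_L4E_TO_L23E_MV = 0.3

# delays (ms): mean and relative standard deviation
DELAY_EXC_MEAN = 1.5
DELAY_INH_MEAN = 0.75
DELAY_REL_SD = 0.5

# LIF parameters (exponential PSCs)
LIF_PARAMS = dict(
    tau_m=10.0,        # ms
    E_L=-65.0,         # mV
    R_m=0.04,          # GOhm (tau_m / C_m, C_m = 250 pF)
    tau_syn=0.5,       # ms
    V_th=-50.0,        # mV
    V_reset=-65.0,     # mV
    t_ref=2.0,         # ms
)
C_M_PF = 250.0

# initial membrane potentials drawn from N(V0_MEAN, V0_SD)
V0_MEAN = -58.0
V0_SD = 10.0


def psc_from_psp(psp_mv, tau_m=LIF_PARAMS["tau_m"],
                 tau_syn=LIF_PARAMS["tau_syn"], r_m=LIF_PARAMS["R_m"]):
    """Exponential-PSC amplitude (pA) producing a given peak PSP (mV).

    The membrane response to I(t) = w exp(-t/tau_syn) peaks at
    t_p = ln(tau_m/tau_syn) tau_m tau_syn / (tau_m - tau_syn); the PSC
    amplitude is the requested PSP divided by the unit-amplitude peak.
    """
    tp = np.log(tau_m / tau_syn) * tau_m * tau_syn / (tau_m - tau_syn)
    unit = r_m * tau_syn / (tau_m - tau_syn) \
        * (np.exp(-tp / tau_m) - np.exp(-tp / tau_syn))
    return psp_mv / unit


W_EXC_PA = float(psc_from_psp(PSP_MEAN_MV))           # ~87.81 pA
W_L4E_TO_L23E_PA = float(psc_from_psp(PSP_L4E_TO_L23E_MV))
W_INH_PA = -G_REL * W_EXC_PA


def pathway_synapse_number(p, n_source, n_target):
    """Number of synapses realizing probability ``p`` allowing multapses."""
    if p <= 0 or n_source == 0 or n_target == 0:
        return 0
    return int(round(np.log(1.0 - p)
                     / np.log(1.0 - 1.0 / (n_source * n_target))))
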