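# Methods

## The spike-buffer delivery algorithm

Time-driven spiking-network simulation spends most of its effort storing
spikes, waiting out their synaptic delays, and delivering them to targets.
The common circular event queue schedules one synaptic event per connection
per spike at emission time; per time step this costs on the order of
N·F·C·dt store/retrieve operations (N nodes, mean rate F, C outgoing
connections per node).  spikesim instead keeps **one output spike buffer per
node**.  A buffered spike is three numbers: a multiplicity, an age `t_s` in
steps, and a group index `i_g`.  Each node's outgoing connections are
partitioned into **connection groups** of equal quantized delay, sorted
ascending; each step every live entry ages by one, and when `t_s` equals the
delay of group `i_g` the spike is staged on the **global spike array** for
that group and `i_g` advances.  Because groups are delay-sorted, one
comparison per entry per step suffices.  The expected number of live entries
per buffer is F·⟨d_max⟩·dt, where ⟨d_max⟩ is the mean (over nodes) of the
largest outgoing delay, so buffer upkeep scales with the delay spread rather
than with the connection count; delivery from the spike array to targets
remains the dominant cost whenever C is large.  Both properties are asserted
by tests (occupancy against the formula at F = 100 Hz, d_max = 2 ms;
delivery equivalence against an independent event-queue oracle on 200
randomized networks).

Implementation note: the per-node buffers are stored as one vectorized
struct-of-arrays table (entry = source, age, group index, multiplicity), and
delivery gathers whole connection groups with one fancy-indexing pass and a
`bincount` scatter per step.  Per-node semantics are unchanged and exposed
through per-node views used by the unit tests.

Conventions: delays are quantized to the grid by round-half-up with a floor
of one step, so a spike emitted at step t on a d-step connection influences
its target's dynamics during step t + d, and the minimum achievable latency
is one step.  Spikes emitted by one node within one step merge into a single
entry with summed multiplicity.  Emission and arrival times are stamped
(step + 1)·dt — the end of the step in which they occur.

## Neuron models and integration

**LIF with exponential PSCs** (`lif_psc_exp`): τ_m V' = −(V−E_L) + R_m
(I_syn + I_e), τ_syn I_syn' = −I_syn + Σ w δ(t−t_f).  The subthreshold
system is linear, so each step applies the closed-form one-step propagator —
no truncation error at any dt (verified to <1e−9 mV over 10⁴ steps against
the analytic superposition).  The degenerate case τ_m = τ_syn uses the
analytic limit R_m·dt·e^(−dt/τ_m)/τ_m.  Threshold is checked on the grid
after propagation; reset pins V at V_reset for round(t_ref/dt) steps while
I_syn keeps evolving.

**AdEx with conductance-based beta/alpha synapses** (`aeif_cond_beta`):
C V' = −g_L(V−E_L) + g_L·Δ_T·exp((V−V_T)/Δ_T) − Σ_i g_i(V−E_rev,i) + I_e − ω,
τ_ω ω' = a(V−E_L) − ω, with per-receptor-port conductances g_i' = h_i −
g_i/τ_decay, h_i' = −h_i/τ_rise (alpha function in the equal-τ limit).  An
incoming spike increments h_i by weight × c_norm, with c_norm chosen so a
unit-weight spike peaks at exactly 1 nS (c_norm = e/τ for the alpha case) —
the peak-normalization convention of the reference conductance models.  The
system is integrated across each network step by the Cash–Karp embedded
4(5) Runge–Kutta pair with per-neuron adaptive internal steps: scaled error
per variable ≤ `error_tol` with scale |y| + |h·y'| + 1 (the one-unit floor
gives absolute control for variables resting at zero), growth factor
0.9·err^(−0.2) capped at 5×, shrink 0.9·err^(−0.25) floored at 0.1×, and an
underflow guard at h = 1e−10 ms.  The exponential argument is capped at
V_peak and at 10 (beyond which the trajectory is runaway and the bounded
slope keeps the crossing integrable).

Spike handling has two modes.  `resolve` (default): the upswing is
integrated under full error control and the V = V_peak crossing inside the
final substep is located by cubic-Hermite dense-output interpolation; reset
(V→V_r, ω→ω+b) is applied at the interpolated crossing and integration
continues for the remainder of the step.  This keeps the trajectory within
1e−4 mV of a 100×-finer fixed-step RK4 reference away from the peaks (the
acceptance test).  `fast` (used by the network builders): once V exceeds an
onset voltage where the exponential slope passes 2 mV/ms, the V and ω error
components are exempted from step-size control — the upswing shape is not
resolved, only the grid-quantized crossing — which removes an ~exp(7)-fold
stiff zone that would otherwise force ~100 substeps per spike.  Population
statistics are insensitive to the choice (the balanced-network mean rate
agrees to <0.2% between modes) while large networks run ~5× faster.
Network builders also default to `error_tol = 1e−6` (single neurons:
1e−8), again with no measurable effect on population statistics.

V_peak defaults to 0 mV and the AdEx refractory time to 0 ms; both are
exposed parameters, as neither is fixed by the published parameter tables.

**Izhikevich** (`izhikevich`): v' = 0.04v² + 5v + 140 − u + I, u' =
a(bv − u), advanced at dt = 1 ms with two 0.5 ms forward-Euler substeps;
v ≥ 30 mV resets v→c, u→u+d (checked after each substep to avoid
overflow).  Synapses are current-based with exponential decay: arrivals add
to I_syn, which is held for the step's substeps and then decays by
exp(−dt/τ_decay).  Initial state is the I = 0 rest point (v₀ solves
0.04v² + 5v + 140 = bv; u₀ = bv₀).

## Plasticity

Symmetric nearest-neighbor STDP.  Each plastic connection stores the arrival
time of its last presynaptic spike (emission + axonal delay, where the
axonal delay is identified with the connection delay served by the spike
buffer); each neuron stores the effect time of its last postsynaptic spike
(spike time + dendritic delay, default 0 ms).  On pre-arrival the depression
branch applies with Δt = last_post − t_now ≤ 0; on post-effect the
potentiation branch applies with Δt = t_now − last_pre ≥ 0; Δt = 0 produces
no change (the closed form has strict inequalities), and weights are clipped
into [0, w_max] after every update.  A multiplicity-m arrival counts as a
single pairing event.  The dendritic delay is uniform per synapse
specification; when synapses of differing dendritic delay converge on one
neuron the per-neuron last-post bookkeeping is shared, an approximation that
vanishes at the default of 0 ms.

## Devices

Poisson generators draw multiplicities with mean rate·dt/1000.  The default
**independent** semantics give every generator→target connection its own
realization (equivalent to a private generator per target), matching the
reference semantics of the benchmark models; a **shared** mode pushes a
single realization through the generator's spike buffer.  Each device owns a
substream derived from (seed, device index), so adding a device never
perturbs connectivity draws or other devices.  Recorders are append-only and
provably (by test) do not alter dynamics.

## Benchmark networks

**AdEx balanced network**: N_ex excitatory and N_ex/4 inhibitory AdEx
neurons; every neuron receives CE fixed-indegree excitatory inputs (weight
W_ex = 0.05 nS on the E_rev = 0 port), CE/4 inhibitory (W_in = 0.35 nS on
the E_rev = −85 mV port), normal delays 0.5 ± 0.25 ms (clipped at one
step), and an independent 20,000 Hz Poisson drive at 0.37 nS.  Weights are
interpreted as peak conductances in nS (the printed table omits units; the
model is conductance-based).  The drive delay is one step (not printed;
irrelevant to stationary statistics).  Initial membrane potentials are
drawn uniformly in [E_L, V_T] to desynchronize the onset transient, which
is discarded before statistics.  At the published operating point the
population settles to ~27–30 Hz asynchronous-irregular firing, matching the
printed 30.7 Hz average within the stochastic tolerance; fixed indegree
makes the rate insensitive to N_ex.

**Izhikevich balanced network with STDP**: same architecture at dt = 1 ms,
100 connections per neuron (80 excitatory with nearest-neighbor STDP at the
printed parameter set, 20 inhibitory static), current-based exponential
synapses (τ_decay = 2 ms).  The published description fixes the 16 Hz
operating point but not the drive or weights, so the builder requires the
Poisson rate and weight; with its documented defaults (w_ex = 1 pA,
w_in = −8 pA, drive 1000 Hz × 2 pA) a 500-neuron network runs at ~15 Hz and
the mean plastic weight moves by <1% of w_max per simulated second.

**Cortical microcircuit**: the eight-population (2/3E…6I) 1 mm² sensory
cortex model, ~77,000 LIF neurons at full scale, built from vendored
constants (sizes, 8×8 connection-probability matrix, external indegrees,
8 Hz background rate, PSP→PSC conversion giving 87.81 pA per 0.15 mV,
delays 1.5 ± 0.75 / 0.75 ± 0.375 ms, exponential-PSC LIF constants).
Pathway synapse counts follow K = ln(1−p)/ln(1−1/(N_pre·N_post)) at the
(scaled) population sizes, realized with fixed_total_number.  Downscaling
is plain proportional scaling of sizes and recurrent counts — no
rate-preserving compensation — but the per-neuron external indegree is kept
at full scale so the reduced network stays active: with the recurrent (net
inhibitory) feedback thinned, the scale-0.1 circuit fires faster than the
full-scale reference, which is expected and documented behavior of naive
downscaling; the acceptance check for the scaled model is structural plus
"every population spikes", not a rate match.

## Validation statistics

Per-neuron firing rate (count/window; silent neurons included at 0 Hz);
CV ISI (population-std convention, ddof = 0; trains with <3 spikes are
excluded, not zeroed); pairwise Pearson correlation of spike-count trains
binned at 2 ms on a seeded 200-neuron subsample (all-zero trains excluded
with a warning); Gaussian KDE with Silverman bandwidth
b = 0.9·min(σ̂, IQR/1.349)·N^(−1/5) (σ̂ with ddof = 1; degenerate samples
fall back to a 1e−3 minimum bandwidth), each kernel carrying integral 1/N;
KL divergence computed in the standard non-negative orientation
∫ p₁ log(p₁/p₂) on a shared grid with the denominator floored at 1e−12 and
both densities renormalized by the trapezoid rule.  The seed-pairing
protocol reduces each run to a 1-D statistic sample, smooths matched pairs
on a common grid, and reports cross-condition KL (pairs (a_i, b_i)) against
the within-condition seed-to-seed band (pairs (a_i, a_{i+1 mod n}));
"compatible" means the cross mean lies within three band-widths
(max of the two standard deviations) of the baseline mean.

## Test oracles and problem sizes

All reference implementations live in `spikesim.oracle` and share no
delivery or integration code with the main path: an exhaustive circular
event queue (per-connection scheduling), a fixed-stride classical RK4
integrator with bisection-resolved threshold crossings, and a complete
second backend for the AdEx balanced network (event queue + fixed-substep
RK4 + its own Poisson draws) used by the seed-compatibility protocol.
Oracles run on desk-scale instances only (≤10³ neurons); consequently the
two-backend comparison uses an 800+200-neuron network with CE = 100 and
weights rescaled ×10 to hold the synaptic drive, and hence the operating
point, of the full-size model.  The test suite checks the balanced-network
rate with 0.4 s of biological time per seed (the rate estimator's standard
error there is ≪1 Hz); the acceptance script simulates the full 1.1 s per
seed with a 0.1 s discard, three seeds.

## Known limitations

Single-process, time-driven only; no multi-compartment models, no
neuromodulation, plasticity beyond nearest-neighbor STDP, or spatially
structured connectivity.  `fixed_total_number` ignores the multapse flag
(draws are with replacement).  Double precision throughout.  The synthetic
benchmark networks emulate stationary asynchronous-irregular activity; they
do not reproduce non-stationary or stimulus-locked regimes, so passing
statistics here demonstrate correctness of the simulation machinery, not
biological completeness of the models.
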