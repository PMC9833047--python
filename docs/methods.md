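# Methods

This note documents the models implemented in `infomaxstdp`, the
numerical conventions, the choices made where the design was open, and
the known limitations of the synthetic settings the test-suite runs in.

## Spiking neuron model

Every neuron is a stochastic point-process unit. Spikes are emitted with
instantaneous density

    rho(t) = g^P(u(t)) * R(t),        P in {E, I}

where the activation intensity is a softplus of the membrane potential,

    g^P(u) = r0^P * log(1 + exp((u - u0^P) / du^P)),

with `r0^E = 1.5 Hz, u0^E = -69.4 mV` for excitatory and
`r0^I = 6.0 Hz, u0^I = -62.5 mV` for inhibitory neurons
(`du = 0.5 mV` for both). The inhibitory population's much higher
threshold is what silences it in down states. The refractory factor

    R(t) = (t - t_hat)^4 / (tau_R^4 + (t - t_hat)^4),   tau_R = 30 ms

suppresses firing after the last spike at `t_hat`; it stands in for
classical refractoriness, afterhyperpolarization and EPSP suppression
alike. The membrane is *not* reset at spikes.

Membranes leak toward `u_r = -70 mV` with `tau_m^E = 25 ms`
(`tau_m^I = 5 ms`); each presynaptic spike adds its weight in mV
instantaneously. Excitatory neurons carry an adaptation current

    dI_a/dt = -I_a / tau_a + beta * S^E(t),   tau_a = 1500 ms,
    beta = 0.0077 mV/ms,

subtracted from du/dt, which slowly terminates up states.

### Discrete-time conventions

* Fixed step `dt = 1 ms` (0.1 ms in the pairing-oracle checks). Decay
  over a bin uses the exact factor `exp(-dt/tau)`, never forward Euler.
* Per-bin spike probability `p = 1 - exp(-rho*dt)` (bounded; the
  alternative `rho*dt` differs by <0.3 % at the modelled rates). At most
  one spike per neuron per bin.
* Within a bin: presynaptic increments → membrane update → intensity →
  spike sampling → trace/weight updates. External (feedforward) spikes
  scheduled for bin t act within bin t, so a presynaptic pulse can drive
  the postsynaptic neuron in the same millisecond, as pairing protocols
  require; recurrent spikes sampled in bin t arrive in bin t+1.
* Forced (evoked) spikes bypass the sampler but update the last-spike
  time, adaptation and every plasticity trace exactly like sampled
  spikes.
* All neurons start at rest with `t_hat = -10,000 ms` (so R ≈ 1 at
  t = 0) and `I_a = 0`; every experiment discards a burn-in
  (10,000 ms; 200,000 ms for full-scale sleep sessions) before
  measuring.

## The infomax plasticity rule

Feedforward weights ascend the gradient of `L = I - lambda * Phi`:
mutual information between pre- and postsynaptic spike trains minus a
quadratic weight cost charged per presynaptic spike. The online form is

    dw_j/dt = alpha * [ C_j(t) B_post(t) - lambda w_j x_j(t) ]
    c_j(t)  = (d log g / du)|_{u(t)} (y(t) - rho(t)) h_j(t)
    C_j(t)  = int_0^{t+} c_j(s) exp(-(t-s)/tau_C) ds
    B_post  = y log(rho/rho_bar) - (rho - rho_bar)

with `alpha = 0.01 (mV)^2`, `tau_C = 100 ms`, `lambda = 0.32 (mV)^-2`,
`h_j` the unit EPSP trace of synapse j, `y` the postsynaptic spike
train, and `rho_bar = g_bar * R` the expected intensity. No homeostatic
term is included. Spikes enter `c_j` and `B_post` as unit point masses
in their bin (same-bin inclusion in `C_j`, the one-sided limit of the
integral); rate terms are multiplied by dt. Because `rho_bar` carries
the same refractory factor as `rho`, the log ratio is computed as
`log(g/g_bar)`, avoiding 0/0 right after a spike.

`alpha` is treated as the single overall scale of the rule; the
dimensional bookkeeping of `C_j B_post` follows from the unit EPSP trace
and intensities in 1/ms.

### The mean intensity g_bar

* *fixed-per-state* (single-neuron experiments): one constant per
  behavioural state, computed by averaging `g(u)` over a long
  background-only calibration run, then frozen. The defaults give
  ≈ 5.9 Hz (up) and ≈ 0.5 Hz (down).
* *population-average* (network experiments): the instantaneous mean of
  `g(u_i)` over the target's local excitatory population, evaluated
  every bin.

A practical limitation, quantified in the tests: the exact rule calls
for the expectation of `g(u)` conditioned on the postsynaptic spike
history. The estimators above ignore that conditioning, which leaves a
small residual drift in the information term (about 3 % of the
cost-term scale for a synapse with no causal influence). This is a
property of the estimator, not of the integrator.

### Analytic pairing oracle

Under simplifying assumptions (constant baseline potential `u0`, a hard
refractory window of length `tau_R`, the EPSP decayed by the time the
window ends, a postsynaptic spike immediately after the presynaptic
volley) the information-term change per pairing is

    g'(u0 + du) * log(1 + dg/g_bar) / (g_bar + dg),

`du` the summed stimulated weight, `dg = g(u0+du) - g(u0)`. A
deterministic stripped-down simulation at dt = 0.1 ms matches this to a
few percent at baselines satisfying the assumptions; at high baselines
(g_bar ≳ 5 Hz) the not-quite-decayed EPSP tail alone accounts for a
~5 % gap, a limit of the analytic simplification rather than of the
simulator. For a linear activation the formula reduces to
`g0 log(1+dg/g_bar)/(g_bar+dg)`, strictly decreasing in `g_bar` — the
depression bias at high firing rates.

## Single-neuron experiments

One postsynaptic neuron; 20 stimulated synapses (0.5 mV initial,
plastic) and 100 background synapses (Poisson at 2.0 / 0.1 Hz for the
up / down state, weights fixed). Design choices where the sources are
silent:

* Background weight 0.5 mV. This reproduces the stated mean intensities
  (100 · 2 Hz · 0.5 mV · 25 ms = 2.5 mV mean depolarization → ≈5.9 Hz
  through the softplus, and ≈0.5 Hz in the down state).
* Trials are independent 500 ms windows with the stimulation at 250 ms
  — long against both `tau_C` and the EPSP, one pairing per trial.
* The "state" here is purely a background-rate setting; no bistability.
* Membrane-manipulation variants (depolarize-in-down etc.) are a
  constant offset added to the postsynaptic potential only, with g_bar
  kept at the unmanipulated state value — the mechanism by which such
  manipulations fail to move the plasticity outcome.

`lambda` is calibrated by bracketed root-finding (Brent) on the mean
pre-only down-state weight change, with common random numbers across
evaluations so the Monte-Carlo objective is a deterministic, monotone
function of lambda; 10^4 trials per evaluation reproduce the default
0.32 to within ~7 %. The calibration is configuration-specific: the
information term is not proportional to the weight, so halving the
weight does not halve the calibrated lambda.

## Slow-wave network

800 E + 200 I neurons in four local networks (200 E + 50 I each).
Within a network: all-to-all E→E (0.16 mV), E→I (0.66 mV), I→E
(-0.14 mV), no I→I, no self-coupling. Between networks: Bernoulli
long-range E→E (p = 0.05) and E→I (p = 0.3) connections at the same
weights (the sources specify one weight per connection class); no
long-range inhibition. Up/down alternation arises from recurrent
bistability gated by the adaptation current; the sparse long-range
excitation partially synchronizes the four networks.

States are classified per network from the mean excitatory membrane
potential with hysteresis thresholds `theta_up = -68.25 mV`,
`theta_down = -69.75 mV` (label persists between thresholds; the prefix
before the first crossing keeps the initial down label, immaterial
after burn-in). A state is *global* when at least two of the other
three networks share it. The membrane-potential distribution is bimodal
with its dip between the thresholds, so the classification is
insensitive to their exact placement.

In-network STDP trials deliver a synchronized pulse to feedforward
synapses on a randomly re-selected E1 neuron during the ongoing
dynamics, with g_bar in population-average mode; each trial is binned
by the focal network's state in the bin of the presynaptic pulse
(trials landing in transitions are kept). Weight changes are read out
400 ms after the pulse (the eligibility trace has decayed to <2 %) and
the synapses reset. Conditions: SF = strong-few (20 × 0.5 mV),
WM = weak-many (40 × 0.09 mV). Trials within one run share the network
realization; the postsynaptic target is re-drawn every trial.

## Sleep reactivation

Populations G and L (40 synapses each, 0.09 mV initial — the WM regime
that governs weak task-related synapses) project onto one task neuron
in E1. Synchronized reactivation events follow a Poisson process whose
rate decays linearly from 7.5 Hz to 5.0 Hz over the session (functional
form unstated in the sources; linear is the parsimonious choice), gated
to the focal network's global-up (G) or local-up (L) bins. Event draws
of G and L are independent. The burn-in contains no events and no
plasticity.

Weight updates of a population apply only in bins of its own permitted
state — G in global-up, L in local-up — reflecting the assumption that
plasticity requires the slow-wave-nested spindles that accompany the
population's reactivation. Without this gating, updates triggered by
G events leak into bins re-annotated local-up when another network
transits mid-episode, and blocking local-up plasticity would spuriously
suppress G consolidation. Blocking conditions additionally suppress the
entire update (information and cost term alike) during the blocked
state and for 50 ms after it ends; traces keep evolving.

Full-scale sessions default to 600 s plus a 200 s plasticity-free
burn-in; the desk-scale experiments in the tests use `scale = 0.2`
(120 s sessions) and 3–5 paired trials. Pairing: every blocking
condition of a trial reuses the same session seed, so the network,
background noise and event draws are shared and between-condition
differences isolate the blocking gate. Task performance is the
cue-evoked firing-rate increase of the task neuron for synchronized
volleys probed at fixed intervals over ongoing network dynamics,
computed in Rao-Blackwellized form: the conditional-intensity
expectation g(u + cue) R - g(u) R averaged over the response windows of
the probe trajectory, rather than sampled evoked spikes. Spiking
networks are chaotic — a single divergent spike decorrelates paired
runs — so counting sampled spikes leaves a quantization noise floor
that swamps desk-scale weight differences; the expectation form removes
the sampling noise entirely, subtracts its baseline exactly, and is
strictly increasing in the summed weight. All readouts of an experiment
share one fixed-seed probe network, making performance a deterministic
function of the weights. The model has no distinct awake regime, so
probing over the sleeping dynamics — sampling all states evenly — is
the package's stand-in for an awake task test; only sign and ordering
comparisons are drawn from it. Reactivation strength is the
event-triggered task-neuron rate in a 50 ms window minus the
state-matched baseline rate outside event windows, reported per session
third.

## Mean-field phase plane

One local network collapses to two membrane variables with population
rates `r_P = g^P(u_P)`:

    tau_E du_E/dt = -(u_E - u_r) + tau_E [W_EE r_E + W_EI r_I + D_E r_sur]/1000 - tau_E I_a
    tau_I du_I/dt = -(u_I - u_r) + tau_I [W_IE r_E + D_I r_sur]/1000

with aggregate couplings `W_EE = 199·0.16`, `W_EI = 50·(-0.14)`,
`W_IE = 200·0.66` mV and long-range drive coefficients
`D_E = 30·0.16`, `D_I = 180·0.66` (expected in-degree × weight).
Approximations, chosen deliberately and affecting absolute rates but
not the orderings the analysis is used for:

* Refractory factor set to 1 (a ≤ tens-of-percent rate compression at
  ≤ 30 Hz).
* Adaptation frozen at `I_a = 0.04 mV/ms`, the session-average value
  measured in the spiking simulation — a quasi-static treatment
  (`tau_a >> tau_m`) at a representative mid-cycle level. The phase
  plane is analysed on a bistable slice; at much smaller or larger
  frozen I_a one of the two states vanishes, which is precisely how the
  full system cycles.
* Surround rate 0.1 Hz (down) / 6 Hz (up), the observed surround-state
  means.

The surround-down plane's two stable points are the global-down and
local-up states; the surround-up plane's are local-down and global-up.
Stability is classified by the 2×2 Jacobian; the up states are
inhibition-stabilized (E-only entry positive, full system stable),
which is why surround drive lowers the up-state potential. Fixed-point
potentials agree with the spiking model's state-conditioned means to
within ~1–2 mV; the local-up point is the least accurate (the frozen
adaptation is furthest from its within-state average there).

## Problem sizes used by the shipped tests

Monte-Carlo sizes in the test-suite and acceptance script are the
package's desk-scale defaults: 10^6 ms calibration runs, 10^4 trials
per lambda evaluation, 1–2 × 10^3 single-neuron trials per curve point,
2.5–6 × 10^3 in-network STDP trials per condition, and three paired
sleep trials at scale 0.2. These sizes keep every sign and ordering
claim resolvable at ≥ 2–4 sigma; absolute magnitudes carry the sampling
error their SEMs state.

## Known limitations

* The `g_bar` estimators ignore spike-history conditioning (see above).
* Recurrent weights are fixed; only feedforward synapses are plastic.
* No spindle dynamics: spindle gating is represented by the permitted-
  state rule of the sleep module.
* No axonal delays, no conductance-based synapses, single-compartment
  neurons.
* The synthetic background (homogeneous Poisson, independent sources)
  lacks the correlations and nonstationarity of in-vivo input; passing
  tests demonstrate the mechanisms under those idealized conditions,
  not quantitative agreement with biological recordings.
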