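"""The four-local-network slow-wave simulator.

800 excitatory and 200 inhibitory stochastic spiking neurons split into
four local networks (200 E + 50 I each). Within a local network the
connectivity is all-to-all without self-coupling and with no I-to-I
connections; between networks only excitatory neurons project, sparsely
(E->E with probability 0.05, E->I with probability 0.3). Excitatory
neurons carry a slow spike-triggered adaptation current that terminates
up states, so each network alternates between a depolarized up state and
a quiescent down state; the sparse long-range excitation partially
synchronizes the four networks, producing a mixture of global and local
slow waves.

Spikes sampled in bin t arrive as instantaneous membrane increments at
the start of bin t+1 (discrete-time recurrent convention); external
feedforward spikes scheduled for bin t arrive within bin t and can drive
the postsynaptic neuron in the same bin, as the pairing protocols
require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import log_activation_derivative
from .params import (
    ActivationParams,
    AdaptationParams,
    E_ACTIVATION,
    I_ACTIVATION,
    KernelParams,
    PlasticityParams,
    RefractoryParams,
)
from .states import HysteresisClassifier

__all__ = [
    "NetworkConfig",
    "ConnectivityMask",
    "SlowWaveNetwork",
    "SimulationResult",
    "PlasticBundle",
    "StdpStateResult",
    "build_network",
    "simulate",
    "run_network_stdp",
    "STATE_NAMES",
]

STATE_NAMES = ("global-down", "local-down", "global-up", "local-up")


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and dynamical parameters of the slow-wave model."""

    n_E: int = 800
    n_I: int = 200
    n_local: int = 4
    w_EE: float = 0.16
    w_EI: float = -0.14
    w_IE: float = 0.66
    p_EE_long: float = 0.05
    p_IE_long: float = 0.3
    act_E: ActivationParams = E_ACTIVATION
    act_I: ActivationParams = I_ACTIVATION
    kernel: KernelParams = field(default_factory=KernelParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    refractory: RefractoryParams = field(default_factory=RefractoryParams)
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_E % self.n_local or self.n_I % self.n_local:
            raise ValueError("population sizes must divide evenly into local networks")
        for p in (self.p_EE_long, self.p_IE_long):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {p} outside [0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_E + self.n_I

    def e_indices(self, net: int) -> np.ndarray:
        per = self.n_E // self.n_local
        return np.arange(net * per, (net + 1) * per)

    def i_indices(self, net: int) -> np.ndarray:
        per = self.n_I // self.n_local
        return self.n_E + np.arange(net * per, (net + 1) * per)


@dataclass
class ConnectivityMask:
    """Weight matrix (row = target, column = source) plus its config."""

    weights: np.ndarray
    config: NetworkConfig

    def long_range_density(self, kind: str) -> float:
        """Realized density of long-range E->E or E->I connections."""
        cfg = self.config
        total, present = 0, 0
        for a in range(cfg.n_local):
            for b in range(cfg.n_local):
                if a == b:
                    continue
                rows = cfg.e_indices(a) if kind == "EE" else cfg.i_indices(a)
                block = self.weights[np.ix_(rows, cfg.e_indices(b))]
                present += np.count_nonzero(block)
                total += block.size
        return present / total


def build_network(config: NetworkConfig, rng: np.random.Generator) -> ConnectivityMask:
    """Draw the connectivity: dense within-network blocks, Bernoulli long range.

    Long-range connections exist only from excitatory neurons and carry
    the same weight as the corresponding within-network connection class.
    """
    n = config.n_total
    W = np.zeros((n, n))
    for a in range(config.n_local):
        e_a, i_a = config.e_indices(a), config.i_indices(a)
        W[np.ix_(e_a, e_a)] = config.w_EE
        W[np.ix_(e_a, i_a)] = config.w_EI
        W[np.ix_(i_a, e_a)] = config.w_IE
        for b in range(config.n_local):
            if b == a:
                continue
            e_b = config.e_indices(b)
            mask_ee = rng.random((len(e_a), len(e_b))) < config.p_EE_long
            W[np.ix_(e_a, e_b)] += config.w_EE * mask_ee
            mask_ie = rng.random((len(i_a), len(e_b))) < config.p_IE_long
            W[np.ix_(i_a, e_b)] += config.w_IE * mask_ie
    np.fill_diagonal(W, 0.0)
    return ConnectivityMask(weights=W, config=config)


class SlowWaveNetwork:
    """Stepwise simulator of the recurrent network.

    Exposes per-bin state so that experiment drivers (STDP trials, sleep
    reactivation) can read membrane potentials, inject external EPSPs
    into single neurons, and force evoked spikes.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator,
                 mask: ConnectivityMask | None = None):
        self.config = config
        self.rng = rng
        self.mask = mask if mask is not None else build_network(config, rng)
        self.W = self.mask.weights
        n = config.n_total
        self.u = np.full(n, config.kernel.u_r)
        self.t_hat = np.full(n, -10_000.0)
        self.I_a = np.zeros(config.n_E)
        self.prev_spikes = np.zeros(n, dtype=bool)
        self.t = 0.0
        self._decay_E = np.exp(-config.dt / config.kernel.tau_m_E)
        self._decay_I = np.exp(-config.dt / config.kernel.tau_m_I)
        self._decay_a = np.exp(-config.dt / config.adaptation.tau_a)
        self._e_slice = slice(0, config.n_E)
        self._i_slice = slice(config.n_E, n)
        self._e_nets = [config.e_indices(k) for k in range(config.n_local)]
        self._i_nets = [config.i_indices(k) for k in range(config.n_local)]
        self.g = np.zeros(n)
        self.R = np.ones(n)
        # per-neuron activation constants (E block first, then I)
        self._r0 = np.concatenate([np.full(config.n_E, config.act_E.r0),
                                   np.full(config.n_I, config.act_I.r0)])
        self._u0 = np.concatenate([np.full(config.n_E, config.act_E.u0),
                                   np.full(config.n_I, config.act_I.u0)])
        self._inv_du = np.concatenate([
            np.full(config.n_E, 1.0 / config.act_E.delta_u),
            np.full(config.n_I, 1.0 / config.act_I.delta_u)])
        self._tau_R4 = config.refractory.tau_R**4
        self._zeros = np.zeros(n)

    def step(self, ext_input: np.ndarray | None = None,
             forced: np.ndarray | None = None) -> np.ndarray:
        """Advance one bin; returns the boolean spike vector of this bin.

        ext_input : optional per-neuron instantaneous increments (mV)
        arriving this bin (external feedforward EPSPs). forced : optional
        boolean mask of neurons that emit an evoked spike this bin;
        forced spikes update the last-spike time and adaptation exactly
        like sampled spikes.
        """
        cfg = self.config
        dt = cfg.dt
        idx = np.flatnonzero(self.prev_spikes)
        inc = self.W.take(idx, axis=1).sum(axis=1) if len(idx) else self._zeros
        if ext_input is not None:
            inc = inc + ext_input
        u_r = cfg.kernel.u_r
        e, i = self._e_slice, self._i_slice
        self.u[e] = u_r + (self.u[e] - u_r) * self._decay_E + inc[e] - self.I_a * dt
        self.u[i] = u_r + (self.u[i] - u_r) * self._decay_I + inc[i]

        z = (self.u - self._u0) * self._inv_du
        self.g = self._r0 * np.logaddexp(0.0, z)
        elapsed = self.t - self.t_hat
        d4 = np.square(np.square(elapsed))
        self.R = d4 / (self._tau_R4 + d4)
        p = -np.expm1(self.g * self.R * (-1e-3 * dt))
        spikes = self.rng.random(cfg.n_total) < p
        if forced is not None:
            spikes |= forced
        self.t_hat[spikes] = self.t
        self.I_a = self.I_a * self._decay_a + cfg.adaptation.beta * spikes[e]
        self.prev_spikes = spikes
        self.t += dt
        return spikes

    def mean_u_E(self) -> np.ndarray:
        """Mean excitatory membrane potential of each local network (mV)."""
        return self.u[:self.config.n_E].reshape(self.config.n_local, -1).mean(axis=1)

    def mean_g_E(self, net: int) -> float:
        """Population-average activation intensity of one E population (Hz)."""
        per = self.config.n_E // self.config.n_local
        return float(self.g[net * per:(net + 1) * per].mean())


@dataclass
class SimulationResult:
    """Recorded traces of a free-running simulation (burn-in discarded)."""

    mean_u_E: np.ndarray      # (n_bins, n_local) mV
    e_counts: np.ndarray      # (n_bins, n_local) spikes per bin
    i_counts: np.ndarray      # (n_bins, n_local)
    mean_I_a: np.ndarray      # (n_bins,) mV/ms, averaged over E neurons
    dt: float
    config: NetworkConfig


def simulate(config: NetworkConfig, duration: float, rng: np.random.Generator,
             burn_in: float = 10_000.0,
             mask: ConnectivityMask | None = None) -> SimulationResult:
    """Free-running slow-wave simulation; records per-network summaries.

    The first ``burn_in`` ms are simulated but not recorded, erasing the
    all-at-rest initial condition.
    """
    net = SlowWaveNetwork(config, rng, mask=mask)
    n_burn = int(round(burn_in / config.dt))
    n_bins = int(round(duration / config.dt))
    for _ in range(n_burn):
        net.step()
    mean_u = np.empty((n_bins, config.n_local))
    e_counts = np.empty((n_bins, config.n_local), dtype=np.int32)
    i_counts = np.empty((n_bins, config.n_local), dtype=np.int32)
    mean_I_a = np.empty(n_bins)
    n_loc = config.n_local
    for t in range(n_bins):
        spikes = net.step()
        mean_u[t] = net.mean_u_E()
        e_counts[t] = spikes[:config.n_E].reshape(n_loc, -1).sum(axis=1)
        i_counts[t] = spikes[config.n_E:].reshape(n_loc, -1).sum(axis=1)
        mean_I_a[t] = net.I_a.mean()
    return SimulationResult(mean_u_E=mean_u, e_counts=e_counts, i_counts=i_counts,
                            mean_I_a=mean_I_a, dt=config.dt, config=config)


class PlasticBundle:
    """A bundle of plastic feedforward synapses onto one network neuron.

    Implements the infomax update with the population-average mean
    intensity (g_bar = mean g over the target's local excitatory
    population). Weight updates can be gated off per bin (plasticity
    blocking); the gate suppresses the whole update, information and
    cost term alike, but the traces keep evolving.
    """

    def __init__(self, n: int, w_init: float, act: ActivationParams,
                 plasticity: PlasticityParams, dt: float, tau_m: float = 25.0):
        self.w = np.full(n, float(w_init))
        self.h = np.zeros(n)
        self.C = np.zeros(n)
        self.act = act
        self.plasticity = plasticity
        self.dt = dt
        self._decay_h = np.exp(-dt / tau_m)
        self._decay_C = np.exp(-dt / plasticity.tau_C)
        self.n_gated_updates = 0   # instrumentation: updates applied
        self.n_blocked_updates = 0  # instrumentation: updates suppressed

    def pre_step(self, pre_spiked: bool) -> float:
        """Advance presynaptic traces; return the summed EPSP increment (mV)."""
        self.h *= self._decay_h
        if pre_spiked:
            self.h += 1.0
            return float(self.w.sum())
        return 0.0

    def post_step(self, y: bool, u: float, g: float, R: float, g_bar: float,
                  pre_spiked: bool, allowed: bool = True) -> None:
        """Trace and weight update given the target neuron's bin outcome."""
        pl = self.plasticity
        sens = log_activation_derivative(u, self.act)
        resid = (1.0 if y else 0.0) - g * R * 1e-3 * self.dt
        self.C = self.C * self._decay_C + sens * resid * self.h
        B = (np.log(g / g_bar) if y else 0.0) - (g - g_bar) * R * 1e-3 * self.dt
        if allowed:
            self.w = self.w + pl.alpha * (self.C * B - pl.lam * self.w
                                          * (1.0 if pre_spiked else 0.0))
            self.n_gated_updates += 1
        else:
            self.n_blocked_updates += 1


@dataclass
class StdpStateResult:
    """Per-state weight changes of in-network STDP trials.

    results maps (state, offset) -> dict(mean, sem, n, dws); offset is a
    signed ms value or None for pre-only. States with too few trials are
    still reported with their n rather than dropped.
    """

    condition: str
    results: dict

    def mean_dw(self, state: str, offset=None) -> float:
        return self.results[(state, offset)]["mean"]


_CONDITIONS = {"SF": (20, 0.5), "WM": (40, 0.09)}


def run_network_stdp(config: NetworkConfig, condition: str, offsets,
                     plasticity: PlasticityParams, rng: np.random.Generator,
                     n_trials: int = 400, trial_interval: float = 500.0,
                     burn_in: float = 10_000.0, focal_net: int = 0,
                     mask: ConnectivityMask | None = None,
                     window: float = 400.0) -> StdpStateResult:
    """STDP trials delivered during ongoing slow-wave dynamics.

    condition selects the stimulated-synapse configuration: "SF" (strong
    and few: 20 synapses at 0.5 mV) or "WM" (weak and many: 40 synapses
    at 0.09 mV). offsets is a sequence of post-minus-pre offsets in ms,
    with None meaning pre-only; trials cycle through it round-robin. For
    every trial a fresh random E neuron of the focal network is the
    postsynaptic target; the trial is binned by the focal network's
    state (up/down crossed with global/local) at the bin of the
    presynaptic pulse. Weight changes are read out ``window`` ms after
    the pulse and the synapses are then reset to their initial weight.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be 'SF' or 'WM', got {condition!r}")
    n_syn, w_init = _CONDITIONS[condition]
    offsets = list(offsets)
    if window >= trial_interval:
        raise ValueError("readout window must be shorter than the trial interval")

    net = SlowWaveNetwork(config, rng, mask=mask)
    classifier = HysteresisClassifier(config.n_local)
    for _ in range(int(round(burn_in / config.dt))):
        net.step()
        classifier.update(net.mean_u_E())

    e_focal = config.e_indices(focal_net)
    results = {(s, off): [] for s in STATE_NAMES for off in offsets}

    interval_bins = int(round(trial_interval / config.dt))
    window_bins = int(round(window / config.dt))
    max_off = max((abs(o) for o in offsets if o is not None), default=0)
    lead_bins = int(round(max_off / config.dt)) + 1

    bundle = None
    trial = None  # (state, offset, pre_bin, target)
    bin_idx = 0
    n_done = 0
    forced_buf = np.zeros(config.n_total, dtype=bool)
    ext_buf = np.zeros(config.n_total)
    while n_done < n_trials:
        if trial is None and bin_idx % interval_bins == 0:
            # schedule the presynaptic pulse far enough ahead that a
            # negative-offset forced post spike still lies in the future
            pre_bin = bin_idx + lead_bins
            offset = offsets[n_done % len(offsets)]
            target = int(rng.choice(e_focal))
            bundle = PlasticBundle(n_syn, w_init, config.act_E, plasticity,
                                   config.dt)
            trial = {"offset": offset, "target": target, "pre_bin": pre_bin,
                     "post_bin": None if offset is None
                     else pre_bin + int(round(offset / config.dt))}
        ext = None
        forced = None
        pre_spiked = False
        if trial is not None:
            pre_spiked = bin_idx == trial["pre_bin"]
            amp = bundle.pre_step(pre_spiked)
            if amp:
                ext_buf[:] = 0.0
                ext_buf[trial["target"]] = amp
                ext = ext_buf
            if trial["post_bin"] is not None and bin_idx == trial["post_bin"]:
                forced_buf[:] = False
                forced_buf[trial["target"]] = True
                forced = forced_buf
        spikes = net.step(ext_input=ext, forced=forced)
        labels = classifier.update(net.mean_u_E())
        if trial is not None:
            tgt = trial["target"]
            bundle.post_step(bool(spikes[tgt]), float(net.u[tgt]),
                             float(net.g[tgt]), float(net.R[tgt]),
                             net.mean_g_E(focal_net), pre_spiked)
            if pre_spiked:
                trial["state"] = labels[focal_net]
            if bin_idx == trial["pre_bin"] + window_bins:
                dw = float(np.mean(bundle.w - w_init))
                results[(trial["state"], trial["offset"])].append(dw)
                trial = None
                n_done += 1
        bin_idx += 1

    out = {}
    for key, dws in results.items():
        arr = np.asarray(dws)
        out[key] = {
            "n": len(arr),
            "mean": float(arr.mean()) if len(arr) else float("nan"),
            "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1
            else float("nan"),
            "dws": arr,
        }
    return StdpStateResult(condition=condition, results=out)
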