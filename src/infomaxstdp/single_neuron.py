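"""Feedforward single-neuron STDP experiments.

One postsynaptic neuron receives two groups of excitatory feedforward
inputs: *stimulated* neurons (plastic weights, fire one synchronized
forced spike per trial) and *background* neurons (fixed weights, Poisson
at a state-dependent rate: 2.0 Hz in the up state, 0.1 Hz in the down
state). The up/down "state" here is purely a background-rate setting;
there is no network bistability in this model.

Trials are simulated in parallel as numpy arrays (one row per trial),
which makes the 10^4-trial Monte-Carlo averages needed for the weight
statistics cheap. Within a 1 ms bin the event order is: presynaptic
increments -> membrane update -> intensity -> postsynaptic spike
(sampled or forced) -> trace and weight updates. Forced (evoked) spikes
bypass the sampler but update the last-spike time and all traces exactly
like sampled spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .dynamics import (
    activation_intensity,
    log_activation_derivative,
    refractory_factor,
)
from .params import (
    ActivationParams,
    E_ACTIVATION,
    KernelParams,
    PlasticityParams,
    RefractoryParams,
)
from .plasticity import MeanIntensityEstimate

__all__ = [
    "FeedforwardConfig",
    "PairingProtocol",
    "StdpCurve",
    "estimate_mean_intensity",
    "run_pairing_trials",
    "run_pairing_trial",
    "calibrate_lambda",
    "measure_stdp_curve",
    "simulate_pairing_information_term",
]


@dataclass(frozen=True)
class FeedforwardConfig:
    """Input configuration of the single-neuron model.

    Defaults: 20 stimulated neurons at 0.5 mV (plastic) and 100
    background neurons at 0.5 mV (fixed), background Poisson rates
    2.0 / 0.1 Hz in the up / down state.
    """

    n_stim: int = 20
    n_background: int = 100
    w_stim: float = 0.5
    w_background: float = 0.5
    background_rate_up: float = 2.0
    background_rate_down: float = 0.1
    act: ActivationParams = E_ACTIVATION
    kernel: KernelParams = field(default_factory=KernelParams)
    refractory: RefractoryParams = field(default_factory=RefractoryParams)

    def __post_init__(self) -> None:
        if self.n_stim <= 0 or self.n_background <= 0:
            raise ValueError("neuron counts must be positive")
        if self.background_rate_up < 0 or self.background_rate_down < 0:
            raise ValueError("background rates must be non-negative")

    def background_rate(self, state: str) -> float:
        if state == "up":
            return self.background_rate_up
        if state == "down":
            return self.background_rate_down
        raise ValueError(f"unknown state {state!r}")


@dataclass(frozen=True)
class PairingProtocol:
    """A stimulation protocol: pre-only, pre-post, or post-pre.

    delta_t is the post-minus-pre spike-time offset in ms (positive for
    pre-post, negative for post-pre, None for pre-only).
    """

    kind: str
    delta_t: float | None = None
    n_trials: int = 1000
    state: str = "down"

    def __post_init__(self) -> None:
        if self.kind not in ("pre-only", "pre-post", "post-pre"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "pre-only" and self.delta_t is not None:
            raise ValueError("pre-only protocol takes no delta_t")
        if self.kind == "pre-post" and not (self.delta_t is not None and self.delta_t > 0):
            raise ValueError("pre-post protocol requires delta_t > 0")
        if self.kind == "post-pre" and not (self.delta_t is not None and self.delta_t < 0):
            raise ValueError("post-pre protocol requires delta_t < 0")
        if self.state not in ("up", "down"):
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class StdpCurve:
    """Mean weight change vs pairing offset, with the pre-only reference."""

    offsets: np.ndarray
    mean_dw: np.ndarray
    sem_dw: np.ndarray
    pre_only_mean: float
    pre_only_sem: float
    state: str

    def __post_init__(self) -> None:
        if np.any(self.sem_dw < 0) or self.pre_only_sem < 0:
            raise ValueError("SEM must be non-negative")


def _background_trace(config: FeedforwardConfig, rate_hz: float, n_bins: int,
                      dt: float, rng, n_trials: int = 1) -> np.ndarray:
    """Weighted background EPSP sum over time, shape (n_trials, n_bins).

    Per bin each of the n_background sources spikes independently with
    p = 1 - exp(-rate*dt); the weighted trace follows the AR(1) recursion
    trace[t] = decay * trace[t-1] + w_bg * counts[t] (increments at bin
    start). The recursion is evaluated with a linear filter.
    """
    p = -np.expm1(-rate_hz * 1e-3 * dt)
    counts = rng.binomial(config.n_background, p, size=(n_trials, n_bins))
    decay = np.exp(-dt / config.kernel.tau_m_E)
    return lfilter([config.w_background], [1.0, -decay], counts, axis=1)


def estimate_mean_intensity(config: FeedforwardConfig, state: str,
                            rng: np.random.Generator,
                            duration: float = 1_000_000.0, dt: float = 1.0,
                            discard: float = 1_000.0) -> MeanIntensityEstimate:
    """Calibrate g_bar for one state by a long background-only run.

    Simulates the membrane under background input alone and averages
    g(u(t)) over the run (the intensity does not depend on postsynaptic
    spiking because the membrane is not reset at spikes). The initial
    transient is discarded.
    """
    n_bins = int(round(duration / dt))
    if n_bins <= 0:
        raise ValueError("duration must cover at least one bin")
    trace = _background_trace(config, config.background_rate(state), n_bins, dt, rng)[0]
    u = config.kernel.u_r + trace
    g = activation_intensity(u, config.act)
    start = int(round(discard / dt))
    g_bar = float(np.mean(g[start:]))
    return MeanIntensityEstimate(g_bar=g_bar, mode="fixed-per-state")


def run_pairing_trials(config: FeedforwardConfig, protocol: PairingProtocol,
                       plasticity: PlasticityParams, rng: np.random.Generator,
                       g_bar: float | None = None, dt: float = 1.0,
                       trial_length: float = 500.0, stim_time: float = 250.0,
                       membrane_offset: float = 0.0) -> np.ndarray:
    """Simulate independent pairing trials; return per-synapse weight changes.

    Each trial runs for ``trial_length`` ms with a fresh background
    realization; the stimulated neurons emit one synchronized forced
    spike at ``stim_time`` and, for pre-post / post-pre protocols, the
    postsynaptic neuron emits a forced spike at ``stim_time + delta_t``.
    ``membrane_offset`` adds a constant current-clamp shift to the
    postsynaptic potential only (the artificial depolarization /
    hyperpolarization manipulations); g_bar stays at the unmanipulated
    state value in that case.

    Returns
    -------
    ndarray, shape (n_trials, n_stim)
        Weight change of every stimulated synapse in every trial (mV).
    """
    if g_bar is None:
        g_bar = estimate_mean_intensity(config, protocol.state, rng).g_bar
    n_trials, n_stim = protocol.n_trials, config.n_stim
    n_bins = int(round(trial_length / dt))
    pre_bin = int(round(stim_time / dt))
    post_bin = None
    if protocol.delta_t is not None:
        post_bin = int(round((stim_time + protocol.delta_t) / dt))
        if not 0 <= post_bin < n_bins:
            raise ValueError("forced postsynaptic spike falls outside the trial window")

    act, ker, ref = config.act, config.kernel, config.refractory
    decay_m = np.exp(-dt / ker.tau_m_E)
    decay_C = np.exp(-dt / plasticity.tau_C)

    bg = _background_trace(config, config.background_rate(protocol.state),
                           n_bins, dt, rng, n_trials=n_trials)
    h = np.zeros((n_trials, n_stim))
    C = np.zeros((n_trials, n_stim))
    w0 = np.full((n_trials, n_stim), config.w_stim)
    w = w0.copy()
    t_hat = np.full(n_trials, -10_000.0)

    for t in range(n_bins):
        h *= decay_m
        pre = t == pre_bin
        if pre:
            h += 1.0
        u = ker.u_r + bg[:, t] + np.sum(w * h, axis=1) + membrane_offset
        g = activation_intensity(u, act)
        R = refractory_factor(t * dt, t_hat, ref)
        p = -np.expm1(-g * R * 1e-3 * dt)
        y = rng.random(n_trials) < p
        if post_bin is not None and t == post_bin:
            y = np.ones(n_trials, dtype=bool)
        # traces: same-bin inclusion of the spike mass in C
        sens = log_activation_derivative(u, act)
        resid = y.astype(float) - g * R * 1e-3 * dt
        C = C * decay_C + (sens * resid)[:, None] * h
        B = np.where(y, np.log(g / g_bar), 0.0) - (g - g_bar) * R * 1e-3 * dt
        w = w + plasticity.alpha * (C * B[:, None] - plasticity.lam * w * (1.0 if pre else 0.0))
        t_hat = np.where(y, t * dt, t_hat)

    return w - w0


def run_pairing_trial(config: FeedforwardConfig, protocol: PairingProtocol,
                      plasticity: PlasticityParams, rng: np.random.Generator,
                      **kwargs) -> np.ndarray:
    """Single-trial convenience wrapper; returns shape (n_stim,)."""
    single = PairingProtocol(kind=protocol.kind, delta_t=protocol.delta_t,
                             n_trials=1, state=protocol.state)
    return run_pairing_trials(config, single, plasticity, rng, **kwargs)[0]


def calibrate_lambda(config: FeedforwardConfig, plasticity: PlasticityParams,
                     seed: int, n_trials: int = 10_000,
                     bracket: tuple[float, float] = (0.0, 2.0),
                     g_bar: float | None = None, xtol: float = 5e-3,
                     state: str = "down") -> float:
    """Root-find the cost coefficient lambda that zeroes the pre-only mean dw.

    The mean stimulated-synapse weight change under pre-only stimulation
    in the target (down) state is monotone decreasing in lambda; common
    random numbers (the same seed for every evaluation) make the
    Monte-Carlo objective a deterministic function of lambda so that
    bracketed root-finding is well posed. Raises if the bracket shows no
    sign change.
    """
    if g_bar is None:
        g_bar = estimate_mean_intensity(
            config, state, np.random.default_rng(seed)).g_bar
    protocol = PairingProtocol(kind="pre-only", n_trials=n_trials, state=state)

    def mean_dw(lam: float) -> float:
        p = PlasticityParams(alpha=plasticity.alpha, lam=lam, tau_C=plasticity.tau_C)
        rng = np.random.default_rng(seed + 1)
        return float(np.mean(run_pairing_trials(config, protocol, p, rng, g_bar=g_bar)))

    lo, hi = bracket
    f_lo, f_hi = mean_dw(lo), mean_dw(hi)
    if not f_lo > 0 > f_hi:
        raise ValueError(
            f"no sign change in lambda bracket {bracket}: f({lo})={f_lo:.3g}, "
            f"f({hi})={f_hi:.3g}")
    return float(brentq(mean_dw, lo, hi, xtol=xtol))


def measure_stdp_curve(config: FeedforwardConfig, offsets, plasticity: PlasticityParams,
                       state: str, rng: np.random.Generator, n_trials: int = 1000,
                       g_bar: float | None = None, **kwargs) -> StdpCurve:
    """Mean +/- SEM weight change per pairing offset, plus the pre-only level.

    Offsets are post-minus-pre times in ms; the sign selects the
    protocol. Large |offsets| should converge to the pre-only reference.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2 for a SEM")
    offsets = np.asarray(offsets, dtype=float)
    if g_bar is None:
        g_bar = estimate_mean_intensity(config, state, rng).g_bar

    def stats(protocol):
        dw = run_pairing_trials(config, protocol, plasticity, rng,
                                g_bar=g_bar, **kwargs).mean(axis=1)
        return float(np.mean(dw)), float(np.std(dw, ddof=1) / np.sqrt(len(dw)))

    means, sems = [], []
    for off in offsets:
        kind = "pre-post" if off > 0 else "post-pre"
        if off == 0:
            raise ValueError("offset 0 is ill-defined; use a signed offset")
        m, s = stats(PairingProtocol(kind=kind, delta_t=float(off),
                                     n_trials=n_trials, state=state))
        means.append(m)
        sems.append(s)
    ref_m, ref_s = stats(PairingProtocol(kind="pre-only", n_trials=n_trials, state=state))
    return StdpCurve(offsets=offsets, mean_dw=np.array(means), sem_dw=np.array(sems),
                     pre_only_mean=ref_m, pre_only_sem=ref_s, state=state)


def simulate_pairing_information_term(u0_baseline: float, delta_u_step: float,
                                      act: ActivationParams = E_ACTIVATION,
                                      dt: float = 0.1, duration: float = 800.0,
                                      tau_m: float = 25.0, tau_R: float = 30.0,
                                      tau_C: float = 100.0) -> float:
    """Stripped-down single-pairing simulation of the information term.

    Deterministic counterpart of the analytic pairing formula: constant
    baseline potential, a synchronous presynaptic volley stepping the
    potential by ``delta_u_step`` at t = 0, a forced postsynaptic spike
    one bin later (the immediate-pairing limit), a hard refractory
    window (R = 0 for tau_R after a spike, 1 otherwise), no spontaneous
    spiking, and lambda = 0. Returns the cumulative information-term
    weight change divided by alpha (units 1/mV), directly comparable to
    ``stdp_closed_form``.
    """
    g_bar = activation_intensity(u0_baseline, act)
    n_bins = int(round(duration / dt))
    decay_m = np.exp(-dt / tau_m)
    decay_C = np.exp(-dt / tau_C)
    h = 0.0
    C = 0.0
    t_hat = -10_000.0
    total = 0.0
    for t_idx in range(n_bins):
        t = t_idx * dt
        h *= decay_m
        if t_idx == 0:
            h += 1.0
        u = u0_baseline + delta_u_step * h
        g = activation_intensity(u, act)
        R = 1.0 if (t - t_hat) >= tau_R else 0.0
        y = t_idx == 1  # forced post spike immediately after the volley
        sens = log_activation_derivative(u, act)
        resid = (1.0 if y else 0.0) - g * R * 1e-3 * dt
        C = C * decay_C + sens * resid * h
        B = (np.log(g / g_bar) if y else 0.0) - (g - g_bar) * R * 1e-3 * dt
        total += C * B
        if y:
            t_hat = t
    return float(total)
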