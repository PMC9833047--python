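"""Post-learning sleep: reactivation-driven consolidation and forgetting.

Two populations of presynaptic "memory" neurons project onto one task
neuron in the E1 population of the slow-wave network. During sleep the
population G re-emits the task cue (a synchronized volley of all its
neurons) as a Poisson event train gated to the focal network's global-up
bins, and the population L likewise in local-up bins; the event rate
declines linearly from 7.5 Hz at the start of sleep to 5.0 Hz at the
end. Feedforward weights follow the infomax rule with the
population-average mean intensity; because global up states have a lower
baseline intensity than local up states, G synapses potentiate while L
synapses depress — consolidation of the globally reactivated memory and
forgetting of the locally reactivated one.

Weight updates are gated by state: a population's synapses update only
in bins of its own permitted state (G in global-up, L in local-up), the
states in which its reactivation events — and the slow-wave-nested
spindles assumed to enable plasticity — occur. Plasticity blocking
experiments additionally suppress the whole weight update (information
and cost term alike) during the blocked state and for a 50 ms margin
after it ends; traces keep running throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkConfig, PlasticBundle, SlowWaveNetwork
from .params import PlasticityParams
from .states import HysteresisClassifier

__all__ = [
    "ReactivationSchedule",
    "TaskPopulations",
    "BlockingCondition",
    "SleepOutcome",
    "run_sleep_session",
    "run_sleep_experiment",
    "task_performance",
    "probe_performance",
    "reactivation_strength",
]

BLOCKING_MODES = ("control", "local-up-blocked", "global-up-blocked")


@dataclass(frozen=True)
class ReactivationSchedule:
    """Linearly decaying Poisson rate of synchronized reactivation events."""

    rate_start: float = 7.5
    rate_end: float = 5.0

    def __post_init__(self) -> None:
        if self.rate_start < 0 or self.rate_end < 0:
            raise ValueError("reactivation rates must be non-negative")

    def rate(self, fraction: float) -> float:
        """Event rate (Hz) at a fraction in [0, 1] of the sleep session."""
        return self.rate_start + (self.rate_end - self.rate_start) * fraction


@dataclass(frozen=True)
class TaskPopulations:
    """Presynaptic memory populations G (global-up) and L (local-up)."""

    n_G: int = 40
    n_L: int = 40
    w_init: float = 0.09

    def __post_init__(self) -> None:
        if self.w_init < 0:
            raise ValueError("initial weights must be non-negative")


@dataclass(frozen=True)
class BlockingCondition:
    """Plasticity-blocking mode with a post-state margin (ms)."""

    mode: str = "control"
    margin: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in BLOCKING_MODES:
            raise ValueError(f"unknown blocking mode {self.mode!r}; "
                             f"expected one of {BLOCKING_MODES}")

    @property
    def blocked_state(self) -> str | None:
        return {"control": None, "local-up-blocked": "local-up",
                "global-up-blocked": "global-up"}[self.mode]


@dataclass
class SleepOutcome:
    """Readouts of one sleep session."""

    times: np.ndarray          # sample times of the weight trajectories (ms)
    w_G: np.ndarray            # mean G weight at those times (mV)
    w_L: np.ndarray
    perf_before: float         # task-neuron rate increase at cue (Hz)
    perf_after: float
    react_strength: dict       # (state, chunk) -> Hz above baseline (or None)
    n_events_G: int
    n_events_L: int
    n_blocked_updates: int     # instrumentation: suppressed update bins

    @property
    def dw_G(self) -> float:
        return float(self.w_G[-1] - self.w_G[0])

    @property
    def dw_L(self) -> float:
        return float(self.w_L[-1] - self.w_L[0])

    @property
    def summed_weight_change(self) -> float:
        """Combined change of the two populations' mean synaptic weights.

        With equally sized populations this is proportional to the change
        of the total feedforward weight (and hence of the cue amplitude).
        """
        return float((self.w_G[-1] - self.w_G[0]) + (self.w_L[-1] - self.w_L[0]))


def task_performance(net: SlowWaveNetwork, task_neuron: int, cue_amplitude: float,
                     n_probes: int = 50, probe_interval: float = 400.0,
                     response_window: float = 50.0) -> float:
    """Expected cue-evoked firing-rate increase of the task neuron (Hz).

    Probes the response to ``n_probes`` synchronized cue volleys
    (instantaneous ``cue_amplitude`` mV EPSP, the summed feedforward
    weight) delivered at fixed intervals while the network runs freely.
    The readout is the conditional-intensity expectation of the evoked
    response given the probe trajectory: in each response-window bin the
    cue would raise the task neuron's intensity from g(u) R to
    g(u + cue(t)) R, and the performance is the window-averaged
    difference. This Rao-Blackwellized form of counting evoked spikes
    carries no spike-sampling noise, subtracts its baseline exactly, and
    is strictly increasing in the cue amplitude, so comparisons between
    weight configurations probed on the same trajectory reflect the
    weights alone. The cue is not injected (the probe is passive), which
    neglects the refractory self-limiting of evoked spikes — immaterial
    for the sign and ordering comparisons this readout serves.
    Advances the network in place.
    """
    cfg = net.config
    dt = cfg.dt
    interval_bins = int(round(probe_interval / dt))
    win_bins = int(round(response_window / dt))
    cue_u = cue_amplitude * np.exp(-np.arange(win_bins) * dt / cfg.kernel.tau_m_E)
    z_scale = 1.0 / cfg.act_E.delta_u
    extra = 0.0  # expected evoked spikes, summed over probes
    for _ in range(n_probes):
        for b in range(interval_bins):
            net.step()
            if b < win_bins:
                u = net.u[task_neuron]
                g_cued = cfg.act_E.r0 * np.logaddexp(
                    0.0, (u + cue_u[b] - cfg.act_E.u0) * z_scale)
                extra += (g_cued - net.g[task_neuron]) * net.R[task_neuron] \
                    * 1e-3 * dt
    return float(extra / (n_probes * win_bins * dt * 1e-3))


def probe_performance(config: NetworkConfig, cue_amplitude: float, seed: int,
                      n_probes: int = 100, burn_in: float = 5_000.0,
                      **kwargs) -> float:
    """Task performance of a given summed cue weight on a fresh probe network.

    Builds a probe network from ``seed`` and measures the cue-evoked rate
    increase with :func:`task_performance`. Using one fixed probe seed for
    every performance readout of an experiment makes performance a
    (nearly) deterministic, monotone function of the summed feedforward
    weight: probe-network noise is shared between readouts and cancels
    in comparisons.
    """
    rng = np.random.default_rng(seed)
    net = SlowWaveNetwork(config, rng)
    for _ in range(int(round(burn_in / config.dt))):
        net.step()
    task_neuron = int(rng.choice(config.e_indices(0)))
    return task_performance(net, task_neuron, cue_amplitude, n_probes=n_probes,
                            **kwargs)


def reactivation_strength(task_spike_bins: np.ndarray, event_bins: dict,
                          state_per_bin: np.ndarray, n_bins: int,
                          dt: float = 1.0, window: float = 50.0,
                          n_chunks: int = 3) -> dict:
    """Event-triggered task-neuron rate above the state-matched baseline.

    For each reactivated state ("global-up", "local-up") and each coarse
    time chunk of the session: rate of the task neuron within ``window``
    ms after reactivation events minus its rate in bins of the same
    state outside the post-event windows. Chunks with no events are
    reported as None.
    """
    spike_mask = np.zeros(n_bins, dtype=bool)
    spike_mask[task_spike_bins] = True
    win_bins = int(round(window / dt))
    edges = np.linspace(0, n_bins, n_chunks + 1).astype(int)
    out = {}
    for state, ev in event_bins.items():
        ev = np.asarray(ev, dtype=int)
        in_window = np.zeros(n_bins, dtype=bool)
        for e in ev:
            in_window[e:e + win_bins] = True
        state_mask = state_per_bin == state
        for c in range(n_chunks):
            lo, hi = edges[c], edges[c + 1]
            sl = slice(lo, hi)
            ev_c = ev[(ev >= lo) & (ev < hi)]
            if len(ev_c) == 0:
                out[(state, c)] = None
                continue
            evoked = spike_mask[sl] & in_window[sl]
            n_evoked_bins = (in_window[sl]).sum()
            base_sel = state_mask[sl] & ~in_window[sl]
            if base_sel.sum() == 0:
                raise ValueError(f"empty baseline window for {state} chunk {c}")
            ev_rate = evoked.sum() / (n_evoked_bins * dt * 1e-3)
            base_rate = (spike_mask[sl] & base_sel).sum() / (base_sel.sum() * dt * 1e-3)
            out[(state, c)] = float(ev_rate - base_rate)
    return out


def run_sleep_session(config: NetworkConfig, populations: TaskPopulations,
                      schedule: ReactivationSchedule, blocking: BlockingCondition,
                      plasticity: PlasticityParams, rng: np.random.Generator,
                      duration: float = 600_000.0, burn_in: float = 200_000.0,
                      focal_net: int = 0, sample_every: float = 100.0,
                      probe_kwargs: dict | None = None,
                      probe_seed: int | None = None) -> SleepOutcome:
    """One sleep session: probe, plastic sleep phase, probe again.

    The network burns in without plasticity or reactivation, task
    performance is probed, then reactivation events drive the infomax
    updates for ``duration`` ms, and performance is probed again. The
    reactivation schedule spans the plastic phase.

    If ``probe_seed`` is given, both performance readouts run on a fresh
    probe network built from that seed (see :func:`probe_performance`),
    so that the before/after comparison shares its probe noise;
    otherwise the probes run inline on the session network.
    """
    probe_kwargs = probe_kwargs or {}
    net = SlowWaveNetwork(config, rng)
    classifier = HysteresisClassifier(config.n_local)
    for _ in range(int(round(burn_in / config.dt))):
        net.step()
        classifier.update(net.mean_u_E())

    task_neuron = int(rng.choice(config.e_indices(focal_net)))
    bundle_G = PlasticBundle(populations.n_G, populations.w_init, config.act_E,
                             plasticity, config.dt)
    bundle_L = PlasticBundle(populations.n_L, populations.w_init, config.act_E,
                             plasticity, config.dt)

    def cue_amplitude() -> float:
        return float(bundle_G.w.sum() + bundle_L.w.sum())

    def probe(amp: float) -> float:
        if probe_seed is not None:
            return probe_performance(config, amp, probe_seed, **probe_kwargs)
        return task_performance(net, task_neuron, amp, **probe_kwargs)

    perf_before = probe(cue_amplitude())

    n_bins = int(round(duration / config.dt))
    sample_bins = int(round(sample_every / config.dt))
    n_samples = n_bins // sample_bins + 1
    times = np.arange(n_samples) * sample_every
    w_G_traj = np.empty(n_samples)
    w_L_traj = np.empty(n_samples)
    w_G_traj[0] = bundle_G.w.mean()
    w_L_traj[0] = bundle_L.w.mean()

    margin_bins = int(round(blocking.margin / config.dt))
    blocked_state = blocking.blocked_state
    last_blocked_bin = -10**9
    ext = np.zeros(config.n_total)
    task_spike_bins = []
    event_bins = {"global-up": [], "local-up": []}
    state_per_bin = np.empty(n_bins, dtype=object)

    state = classifier.update(net.mean_u_E())[focal_net]
    for t in range(n_bins):
        frac = t / max(n_bins - 1, 1)
        p_event = -np.expm1(-schedule.rate(frac) * 1e-3 * config.dt)
        # gate events on the focal network's state in the previous bin
        g_event = state == "global-up" and rng.random() < p_event
        l_event = state == "local-up" and rng.random() < p_event
        amp = bundle_G.pre_step(g_event) + bundle_L.pre_step(l_event)
        if amp:
            ext[task_neuron] = amp
            spikes = net.step(ext_input=ext)
            ext[task_neuron] = 0.0
        else:
            spikes = net.step()
        state = classifier.update(net.mean_u_E())[focal_net]
        state_per_bin[t] = state
        if blocked_state is not None and state == blocked_state:
            last_blocked_bin = t
        not_blocked = blocked_state is None or \
            (state != blocked_state and t - last_blocked_bin > margin_bins)
        # updates apply only at reactivation events in the population's
        # permitted state: G consolidates in global-up bins, L in
        # local-up bins, and never while blocked
        allowed_G = not_blocked and state == "global-up"
        allowed_L = not_blocked and state == "local-up"
        y = bool(spikes[task_neuron])
        u, g, R = float(net.u[task_neuron]), float(net.g[task_neuron]), \
            float(net.R[task_neuron])
        g_bar = net.mean_g_E(focal_net)
        bundle_G.post_step(y, u, g, R, g_bar, g_event, allowed_G)
        bundle_L.post_step(y, u, g, R, g_bar, l_event, allowed_L)
        if y:
            task_spike_bins.append(t)
        if g_event:
            event_bins["global-up"].append(t)
        if l_event:
            event_bins["local-up"].append(t)
        if (t + 1) % sample_bins == 0:
            idx = (t + 1) // sample_bins
            if idx < n_samples:
                w_G_traj[idx] = bundle_G.w.mean()
                w_L_traj[idx] = bundle_L.w.mean()

    react = reactivation_strength(np.array(task_spike_bins, dtype=int), event_bins,
                                  state_per_bin, n_bins, dt=config.dt)
    perf_after = probe(cue_amplitude())
    return SleepOutcome(
        times=times, w_G=w_G_traj, w_L=w_L_traj,
        perf_before=perf_before, perf_after=perf_after,
        react_strength=react,
        n_events_G=len(event_bins["global-up"]),
        n_events_L=len(event_bins["local-up"]),
        n_blocked_updates=bundle_G.n_blocked_updates,
    )


def run_sleep_experiment(config: NetworkConfig, plasticity: PlasticityParams,
                         seed: int, conditions=BLOCKING_MODES, n_trials: int = 8,
                         scale: float = 1.0,
                         populations: TaskPopulations = TaskPopulations(),
                         schedule: ReactivationSchedule = ReactivationSchedule(),
                         duration: float = 600_000.0, burn_in: float = 200_000.0,
                         probe_kwargs: dict | None = None) -> dict:
    """Sleep sessions per blocking condition; summary statistics.

    ``scale`` shrinks the session and burn-in durations proportionally
    for desk-scale runs; sign and ordering readouts are preserved at
    scale >= ~0.1. Trials are paired across conditions: trial t of every
    condition uses the same session seed (identical network, background
    noise and reactivation draws), so between-condition differences
    isolate the effect of the blocking gate; all performance readouts of
    the experiment share one fixed-seed probe network, acting as a single
    (nearly deterministic, monotone in the summed weight) measurement
    device so that performance comparisons mirror weight comparisons
    rather than probe noise. Returns
    {condition: {dw_G, dw_L, dsum, dperf (means), *_sem, outcomes}}.
    """
    results = {}
    for mode in conditions:
        outs = []
        for trial in range(n_trials):
            rng = np.random.default_rng([seed, trial])
            out = run_sleep_session(
                config, populations, schedule, BlockingCondition(mode=mode),
                plasticity, rng, duration=duration * scale,
                burn_in=burn_in * scale, probe_kwargs=probe_kwargs,
                probe_seed=seed)
            outs.append(out)
        dG = np.array([o.dw_G for o in outs])
        dL = np.array([o.dw_L for o in outs])
        dsum = np.array([o.summed_weight_change for o in outs])
        dperf = np.array([o.perf_after - o.perf_before for o in outs])

        def m_s(x):
            return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))

        results[mode] = {
            "dw_G": m_s(dG)[0], "dw_G_sem": m_s(dG)[1],
            "dw_L": m_s(dL)[0], "dw_L_sem": m_s(dL)[1],
            "dsum": m_s(dsum)[0], "dsum_sem": m_s(dsum)[1],
            "dperf": m_s(dperf)[0], "dperf_sem": m_s(dperf)[1],
            "outcomes": outs,
        }
    return results
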