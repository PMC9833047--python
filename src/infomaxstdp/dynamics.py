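"""Discrete-time primitives of the stochastic spiking neuron.

The neuron fires as an inhomogeneous point process with intensity
rho(t) = g(u(t)) * R(t): a softplus function g of the membrane potential
gated by a quartic refractory factor R. The membrane integrates EPSPs as
instantaneous jumps that decay exponentially; excitatory neurons carry a
slow spike-triggered adaptation current.

Conventions (shared by every simulator in this package):

* time step dt = 1 ms by default; decay over a bin is applied as the
  exact exponential factor, never a forward-Euler approximation;
* spike increments are added at the start of a bin, so a presynaptic
  spike at t can raise the postsynaptic intensity at t;
* per-bin spike probability is p = 1 - exp(-rho * dt) (bounded, correct
  small-dt limit); at most one spike per neuron per bin;
* rates are expressed in Hz at the API surface and converted to 1/ms
  internally where they multiply dt.
"""

from __future__ import annotations

import numpy as np

from .params import ActivationParams, AdaptationParams, RefractoryParams

__all__ = [
    "softplus",
    "activation_intensity",
    "activation_derivative",
    "log_activation_derivative",
    "refractory_factor",
    "epsp_kernel",
    "sample_spike",
    "step_adaptation",
    "decay_factor",
]


def softplus(z):
    """Numerically safe log(1 + exp(z)), elementwise."""
    z = np.asarray(z, dtype=float)
    # For z > ~30, log1p(exp(z)) == z to double precision.
    out = np.where(z > 30.0, z, np.log1p(np.exp(np.minimum(z, 30.0))))
    return out if out.ndim else float(out)


def activation_intensity(u, params: ActivationParams):
    """Softplus activation intensity g(u) = r0 * log(1 + exp((u - u0)/delta_u)).

    Parameters
    ----------
    u : float or ndarray
        Membrane potential in mV.
    params : ActivationParams

    Returns
    -------
    float or ndarray
        Firing intensity in Hz; strictly positive and increasing in u.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("membrane potential must be finite")
    return params.r0 * softplus((u - params.u0) / params.delta_u)


def activation_derivative(u, params: ActivationParams):
    """dg/du = (r0/delta_u) * sigmoid((u - u0)/delta_u), in Hz/mV."""
    u = np.asarray(u, dtype=float)
    z = (u - params.u0) / params.delta_u
    sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                   np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    out = (params.r0 / params.delta_u) * sig
    return out if out.ndim else float(out)


def log_activation_derivative(u, params: ActivationParams):
    """d log g / du = g'(u) / g(u), in 1/mV.

    This is the per-mV sensitivity of the log-intensity that weights the
    presynaptic trace in the plasticity rule's auxiliary variable.
    """
    g = activation_intensity(u, params)
    return activation_derivative(u, params) / g


def refractory_factor(t, t_hat, params: RefractoryParams = RefractoryParams()):
    """Quartic refractory factor R = (t - t_hat)^4 / (tau_R^4 + (t - t_hat)^4).

    Zero at the spike time, 1/2 at tau_R, approaching one as the elapsed
    time grows. Raises if t < t_hat (spike in the future).
    """
    dt = np.asarray(t, dtype=float) - np.asarray(t_hat, dtype=float)
    if np.any(dt < 0):
        raise ValueError("t must not precede the last spike time t_hat")
    d4 = dt**4
    out = d4 / (params.tau_R**4 + d4)
    return out if out.ndim else float(out)


def epsp_kernel(t, tau_m: float = 25.0):
    """Causal exponential EPSP kernel: exp(-t/tau_m) for t >= 0, else 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau_m), 0.0)
    return out if out.ndim else float(out)


def sample_spike(rate_density, R, dt, rng, forced=False):
    """Bernoulli spike draw with success probability 1 - exp(-rho*R*dt).

    Parameters
    ----------
    rate_density : float or ndarray
        g(u) in Hz.
    R : float or ndarray
        Refractory factor in [0, 1].
    dt : float
        Bin width in ms.
    rng : numpy.random.Generator
    forced : bool or ndarray of bool
        Where True, the spike occurs regardless of the intensity (evoked
        spikes of the pairing protocols). Forced spikes must still update
        t_hat, adaptation and plasticity traces downstream.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rho = np.asarray(rate_density, dtype=float) * np.asarray(R, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rate density must be non-negative")
    p = -np.expm1(-rho * 1e-3 * dt)  # Hz -> 1/ms
    spikes = rng.random(p.shape if p.ndim else None) < p
    spikes = np.logical_or(spikes, forced)
    return spikes if np.ndim(spikes) else bool(spikes)


def step_adaptation(I_a, spiked, params: AdaptationParams, dt: float):
    """One bin of the adaptation current: exact exponential decay + beta per spike."""
    I_a = np.asarray(I_a, dtype=float)
    if np.any(I_a < 0):
        raise ValueError("adaptation current must be non-negative")
    out = I_a * np.exp(-dt / params.tau_a) + params.beta * np.asarray(spiked, dtype=float)
    return out if out.ndim else float(out)


def decay_factor(tau: float, dt: float) -> float:
    """Exact per-bin exponential decay factor exp(-dt/tau)."""
    return float(np.exp(-dt / tau))
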