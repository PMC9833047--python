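"""The information-maximization (infomax) synaptic plasticity rule.

The rule ascends the gradient of L = I - lambda * Phi, the mutual
information between pre- and postsynaptic spike trains minus a quadratic
weight cost charged per presynaptic spike:

    dw_j/dt = alpha * [ C_j(t) * B_post(t) - lambda * w_j * x_j(t) ]

with the eligibility trace C_j an exponential low-pass (tau_C = 100 ms)
of the auxiliary variable

    c_j(t) = (d log g(u)/du) * (y(t) - rho(t)) * h_j(t)

and the postsynaptic novelty factor

    B_post(t) = y(t) * log(rho(t)/rho_bar(t)) - (rho(t) - rho_bar(t)).

Here y is the postsynaptic spike train (unit point masses), rho = g(u)*R
the instantaneous intensity, and rho_bar = g_bar * R the expected
intensity given the postsynaptic history. Because rho_bar carries the
same refractory factor R as rho, the log ratio reduces to
log(g(u)/g_bar) and is well defined even as R -> 0.

Discretization: spikes contribute unit point mass to c_j and B_post in
their bin; rate terms are multiplied by dt. A spike's contribution to
C_j is included in the same bin (the rule's one-sided limit), which is
what makes a pre-before-post pairing within one eligibility window
potentiate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    activation_derivative,
    activation_intensity,
    log_activation_derivative,
)
from .params import ActivationParams, PlasticityParams

__all__ = [
    "SynapseState",
    "MeanIntensityEstimate",
    "post_factor",
    "population_mean_intensity",
    "c_increment",
    "eligibility_update",
    "weight_update",
    "stdp_closed_form",
]


@dataclass
class SynapseState:
    """State of one plastic feedforward synapse.

    w : EPSP amplitude (mV); h : EPSP trace (dimensionless, jumps by 1
    per presynaptic spike); C : eligibility trace.
    """

    w: float
    h: float = 0.0
    C: float = 0.0


@dataclass(frozen=True)
class MeanIntensityEstimate:
    """Expected activation intensity g_bar used as the novelty baseline.

    mode is "fixed-per-state" (single-neuron experiments: one constant
    per behavioural state, obtained from a calibration run) or
    "population-average" (network experiments: instantaneous mean of
    g(u_i) over the local excitatory population).
    """

    g_bar: float
    mode: str = "fixed-per-state"

    def __post_init__(self) -> None:
        if not self.g_bar > 0:
            raise ValueError(f"g_bar must be positive, got {self.g_bar}")
        if self.mode not in ("fixed-per-state", "population-average"):
            raise ValueError(f"unknown mode {self.mode!r}")


def population_mean_intensity(u_values, act: ActivationParams) -> MeanIntensityEstimate:
    """Instantaneous population-average mean intensity.

    The network experiments estimate g_bar as the mean of g(u_i) over
    the local excitatory population at the current bin.
    """
    u_values = np.asarray(u_values, dtype=float)
    if u_values.size == 0:
        raise ValueError("population is empty; cannot estimate mean intensity")
    return MeanIntensityEstimate(
        g_bar=float(np.mean(activation_intensity(u_values, act))),
        mode="population-average")


def post_factor(y_spiked, g, g_bar, R, dt):
    """Per-bin increment of the postsynaptic factor B_post.

    Parameters
    ----------
    y_spiked : bool or ndarray of bool
        Whether the postsynaptic neuron spiked in this bin.
    g, g_bar : float or ndarray
        Instantaneous and expected activation intensity, Hz. The log
        ratio uses g/g_bar directly (the refractory factor cancels).
    R : float or ndarray
        Refractory factor, used by the rate term rho - rho_bar = (g - g_bar)*R.
    dt : float
        Bin width, ms.

    Returns
    -------
    Spike bins contribute log(g/g_bar) as unit point mass; every bin
    contributes -(g - g_bar) * R * dt (rates converted from Hz).
    """
    y = np.asarray(y_spiked, dtype=bool)
    g = np.asarray(g, dtype=float)
    g_bar = np.asarray(g_bar, dtype=float)
    if np.any(y & (g * np.asarray(R, dtype=float) <= 0)):
        raise ValueError("postsynaptic spike recorded in a bin with zero intensity")
    rate_term = -(g - g_bar) * np.asarray(R, dtype=float) * 1e-3 * dt
    spike_term = np.where(y, np.log(np.where(y, g, 1.0) / g_bar), 0.0)
    out = spike_term + rate_term
    return out if out.ndim else float(out)


def c_increment(y_spiked, g, R, u, h, act: ActivationParams, dt):
    """Per-bin mass of the auxiliary variable c_j.

    c_j = (d log g/du)|_u * (y - rho*dt) * h_j, with the spike indicator
    as unit point mass and rho = g*R in Hz converted per bin.
    """
    y = np.asarray(y_spiked, dtype=float)
    h = np.asarray(h, dtype=float)
    sens = log_activation_derivative(u, act)  # 1/mV
    residual = y - np.asarray(g, dtype=float) * np.asarray(R, dtype=float) * 1e-3 * dt
    out = sens * residual * h
    return out if np.ndim(out) else float(out)


def eligibility_update(C, c_inc, dt, params: PlasticityParams):
    """Exponential low-pass of c_j with tau_C; same-bin inclusion of spikes.

    C(t) <- C(t - dt) * exp(-dt/tau_C) + c_inc(t), so a spike's mass at
    time t is already visible in C(t) (the lim eps->+0 convention).
    """
    return np.asarray(C, dtype=float) * np.exp(-dt / params.tau_C) + c_inc


def weight_update(w, C, B_inc, pre_spiked, params: PlasticityParams):
    """Per-bin weight change: dw = alpha * (C * B_inc - lam * w * x).

    The cost term fires only in bins with a presynaptic spike.
    """
    x = np.asarray(pre_spiked, dtype=float)
    dw = params.alpha * (np.asarray(C, dtype=float) * np.asarray(B_inc, dtype=float)
                         - params.lam * np.asarray(w, dtype=float) * x)
    return np.asarray(w, dtype=float) + dw


def stdp_closed_form(u0_baseline, delta_u_step, act: ActivationParams):
    """Analytic information-term weight change for one pre-post pairing.

    Under the simplifications of the theory (constant baseline potential
    u0, hard refractory window longer than the EPSP, postsynaptic spike
    immediately after the synchronous presynaptic volley that steps the
    potential by delta_u_step):

        dw_info / alpha = g'(u0 + du) * log(1 + dg/g_bar) / (g_bar + dg)

    with g_bar = g(u0) and dg = g(u0 + du) - g_bar. The value is in
    1/mV per pairing (multiply by alpha for the weight change in mV).
    Potentiation per pairing decreases with the baseline intensity
    g_bar — the depression bias at high mean rates.
    """
    if np.any(np.asarray(delta_u_step) < 0):
        raise ValueError("delta_u_step must be non-negative")
    g_bar = activation_intensity(u0_baseline, act)
    if np.any(np.asarray(g_bar) <= 0):
        raise ValueError("baseline intensity g_bar must be positive")
    g_peak = activation_intensity(np.asarray(u0_baseline) + np.asarray(delta_u_step), act)
    dg = g_peak - g_bar
    out = activation_derivative(np.asarray(u0_baseline) + np.asarray(delta_u_step), act) \
        * np.log1p(dg / g_bar) / (g_bar + dg)
    return out if np.ndim(out) else float(out)


def stdp_closed_form_linear(g0, g_bar, dg):
    """Closed-form pairing change for a linear activation g = g0 * (u - u_r).

    Equals g0 * log(1 + dg/g_bar) / (g_bar + dg); with g0 = g_bar = dg = 1
    this is (1/2) * ln 2. Exposed mainly as an analytic cross-check.
    """
    if g_bar <= 0:
        raise ValueError("g_bar must be positive")
    return g0 * np.log1p(dg / g_bar) / (g_bar + dg)
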