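"""Parameter containers for the stochastic spiking-neuron model.

All voltages are in mV, times in ms, rates in Hz unless noted. The
defaults are the standard parameter set of the model: a softplus escape
rate with population-specific threshold/scale, a quartic refractory
factor, exponential EPSP kernels, and a slow spike-triggered adaptation
current on excitatory neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ActivationParams:
    """Softplus activation intensity g(u) = r0 * log(1 + exp((u - u0)/delta_u)).

    Parameters
    ----------
    r0 : float
        Rate scale in Hz. Must be positive.
    u0 : float
        Soft threshold in mV.
    delta_u : float
        Slope width in mV. Must be positive.
    population_tag : str
        "E" (excitatory) or "I" (inhibitory).
    """

    r0: float
    u0: float
    delta_u: float
    population_tag: str = "E"

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if not self.delta_u > 0:
            raise ValueError(f"delta_u must be positive, got {self.delta_u}")
        if self.population_tag not in ("E", "I"):
            raise ValueError(f"population_tag must be 'E' or 'I', got {self.population_tag!r}")


#: Excitatory activation: r0 = 1.5 Hz, u0 = -69.4 mV, delta_u = 0.5 mV.
E_ACTIVATION = ActivationParams(r0=1.5, u0=-69.4, delta_u=0.5, population_tag="E")

#: Inhibitory activation: r0 = 6.0 Hz, u0 = -62.5 mV, delta_u = 0.5 mV.
#: The higher threshold keeps inhibitory cells silent in down states.
I_ACTIVATION = ActivationParams(r0=6.0, u0=-62.5, delta_u=0.5, population_tag="I")


@dataclass(frozen=True)
class RefractoryParams:
    """Quartic refractory recovery R(t) = dt^4 / (tau_R^4 + dt^4), dt = t - t_hat."""

    tau_R: float = 30.0

    def __post_init__(self) -> None:
        if not self.tau_R > 0:
            raise ValueError(f"tau_R must be positive, got {self.tau_R}")


@dataclass(frozen=True)
class KernelParams:
    """Membrane / EPSP kernel constants.

    tau_m_E is both the excitatory membrane time constant and the EPSP
    decay; tau_m_I is the (faster) inhibitory membrane time constant;
    u_r is the common resting potential.
    """

    tau_m_E: float = 25.0
    tau_m_I: float = 5.0
    u_r: float = -70.0

    def __post_init__(self) -> None:
        if not (self.tau_m_E > 0 and self.tau_m_I > 0):
            raise ValueError("membrane time constants must be positive")


@dataclass(frozen=True)
class AdaptationParams:
    """Spike-triggered adaptation current: dI_a/dt = -I_a/tau_a + beta * S(t).

    Excitatory neurons only. beta is the per-spike increment in mV/ms;
    the slow decay (tau_a = 1500 ms) paces the up/down alternation.
    """

    tau_a: float = 1500.0
    beta: float = 0.0077

    def __post_init__(self) -> None:
        if not self.tau_a > 0:
            raise ValueError(f"tau_a must be positive, got {self.tau_a}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


@dataclass(frozen=True)
class PlasticityParams:
    """Infomax-rule constants.

    alpha : learning rate, (mV)^2.
    lam : weight-cost coefficient, 1/(mV)^2. The default 0.32 is the
        value at which pre-only stimulation in the down state of the
        single-neuron model produces zero mean weight change.
    tau_C : eligibility-trace time constant, ms.
    """

    alpha: float = 0.01
    lam: float = 0.32
    tau_C: float = 100.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.lam < 0:
            raise ValueError(f"lam must be non-negative, got {self.lam}")
        if not self.tau_C > 0:
            raise ValueError(f"tau_C must be positive, got {self.tau_C}")


@dataclass
class NeuronState:
    """Mutable state of one neuron: membrane potential, last spike, adaptation."""

    u: float = -70.0
    t_hat: float = -10_000.0
    I_a: float = 0.0


def params_to_dict(p) -> dict:
    """Flatten a parameter dataclass to a plain dict (for config snapshots)."""
    return asdict(p)
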