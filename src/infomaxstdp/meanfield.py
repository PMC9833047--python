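"""Rate-based mean-field reduction of one local network.

Collapses the 200 E + 50 I neurons of one local network onto two
membrane variables (u_E, u_I) with population rates r_P = g^P(u_P)
(the refractory factor is approximated as one — a modest rate
compression at the <=30 Hz rates involved that does not affect the
orderings of interest):

    du_E/dt = -(u_E - u_r)/tau_E + [W_EE g_E(u_E) + W_EI g_I(u_I)
              + D_E r_sur]/1000 - I_a
    du_I/dt = -(u_I - u_r)/tau_I + [W_IE g_E(u_E) + D_I r_sur]/1000

with aggregate couplings W_EE = (n_E/4 - 1) w_EE etc. (mV per
population spike), long-range drive coefficients D_P = (expected
long-range in-degree) * weight, the surrounding networks' mean rate
r_sur set to a down- or up-state value, and the adaptation current
frozen at a quasi-static value (tau_a >> tau_m).

The two stable intersections of the nullclines are the down and up
states; with the surround down they are the global-down and local-up
points, with the surround up the local-down and global-up points. The
up state is inhibition-stabilized: the E subsystem alone is unstable
and feedback inhibition stabilizes it, which is why long-range
excitation *lowers* the up-state excitatory potential (global up below
local up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .dynamics import activation_derivative, activation_intensity
from .params import ActivationParams, E_ACTIVATION, I_ACTIVATION, KernelParams

__all__ = ["MeanFieldConfig", "FixedPoint", "nullclines", "find_fixed_points",
           "isn_diagnostics"]


@dataclass(frozen=True)
class MeanFieldConfig:
    """Aggregate couplings and drives of the two-variable rate model.

    Defaults are the collapse of the standard network configuration:
    W_EE = 199 * 0.16, W_EI = 50 * (-0.14), W_IE = 200 * 0.66 (mV);
    long-range in-degrees 0.05 * 600 = 30 (onto E) and 0.3 * 600 = 180
    (onto I) times their weights. The surround rates and the frozen
    adaptation current are representative values from the spiking
    simulation (near-silent surround in down states, ~6 Hz in up
    states; adaptation at its session-average level).
    """

    W_EE: float = 199 * 0.16
    W_EI: float = 50 * -0.14
    W_IE: float = 200 * 0.66
    D_E: float = 30 * 0.16
    D_I: float = 180 * 0.66
    surround_rate_down: float = 0.1
    surround_rate_up: float = 6.0
    I_a_frozen: float = 0.04
    act_E: ActivationParams = E_ACTIVATION
    act_I: ActivationParams = I_ACTIVATION
    kernel: KernelParams = field(default_factory=KernelParams)

    @classmethod
    def from_network(cls, net_config, **overrides) -> "MeanFieldConfig":
        """Collapse a NetworkConfig onto aggregate mean-field couplings."""
        n_e = net_config.n_E // net_config.n_local
        n_i = net_config.n_I // net_config.n_local
        n_far = net_config.n_E - n_e
        return cls(
            W_EE=(n_e - 1) * net_config.w_EE,
            W_EI=n_i * net_config.w_EI,
            W_IE=n_e * net_config.w_IE,
            D_E=net_config.p_EE_long * n_far * net_config.w_EE,
            D_I=net_config.p_IE_long * n_far * net_config.w_IE,
            act_E=net_config.act_E, act_I=net_config.act_I,
            kernel=net_config.kernel, **overrides)

    def surround_rate(self, surround: str) -> float:
        if surround == "down":
            return self.surround_rate_down
        if surround == "up":
            return self.surround_rate_up
        raise ValueError(f"surround must be 'down' or 'up', got {surround!r}")


@dataclass
class FixedPoint:
    """A steady state of the mean-field system."""

    u_E: float
    u_I: float
    stable: bool
    residual: float

    @property
    def rate_E(self) -> float:
        return float(activation_intensity(self.u_E, E_ACTIVATION))


def _drift(u_E, u_I, config: MeanFieldConfig, r_sur: float):
    ker = config.kernel
    g_E = activation_intensity(u_E, config.act_E)
    g_I = activation_intensity(u_I, config.act_I)
    du_E = (-(u_E - ker.u_r) / ker.tau_m_E
            + (config.W_EE * g_E + config.W_EI * g_I + config.D_E * r_sur) * 1e-3
            - config.I_a_frozen)
    du_I = (-(u_I - ker.u_r) / ker.tau_m_I
            + (config.W_IE * g_E + config.D_I * r_sur) * 1e-3)
    return du_E, du_I


def _jacobian(u_E, u_I, config: MeanFieldConfig):
    ker = config.kernel
    dg_E = activation_derivative(u_E, config.act_E)
    dg_I = activation_derivative(u_I, config.act_I)
    return np.array([
        [-1 / ker.tau_m_E + config.W_EE * dg_E * 1e-3, config.W_EI * dg_I * 1e-3],
        [config.W_IE * dg_E * 1e-3, -1 / ker.tau_m_I],
    ])


def nullclines(config: MeanFieldConfig, surround: str,
               grid=None) -> dict[str, np.ndarray]:
    """E- and I-nullclines as point sets over a u_E grid.

    The I-nullcline is explicit: u_I = u_r + tau_I*(W_IE g_E(u_E) + D_I
    r_sur)/1000. The E-nullcline solves du_E/dt = 0 for u_I at each u_E
    by inverting the softplus (points where no inhibition level can
    balance the drift are omitted; an entirely empty curve is possible
    for extreme couplings).
    """
    if grid is None:
        grid = np.linspace(-72.0, -60.0, 241)
    grid = np.asarray(grid, dtype=float)
    r_sur = config.surround_rate(surround)
    ker, act_I = config.kernel, config.act_I

    i_null = ker.u_r + ker.tau_m_I * (
        config.W_IE * activation_intensity(grid, config.act_E)
        + config.D_I * r_sur) * 1e-3

    e_points = []
    for u_E in grid:
        # required inhibitory intensity to null the E drift
        g_E = activation_intensity(u_E, config.act_E)
        need = ((u_E - ker.u_r) / ker.tau_m_E + config.I_a_frozen) * 1e3 \
            - config.W_EE * g_E - config.D_E * r_sur
        # need = W_EI * g_I ; W_EI < 0 so g_I = need / W_EI must be >= 0
        if config.W_EI == 0:
            continue
        g_I = need / config.W_EI
        if g_I <= 0:
            continue
        z = np.log(np.expm1(g_I / config.act_I.r0))
        u_I = act_I.u0 + act_I.delta_u * z
        e_points.append((u_E, u_I))
    return {"E": np.array(e_points).reshape(-1, 2),
            "I": np.column_stack([grid, i_null])}


def find_fixed_points(config: MeanFieldConfig, surround: str,
                      guesses=None, tol: float = 1e-10) -> list[FixedPoint]:
    """Locate and classify the steady states for one surround condition.

    Roots of the two-variable drift are found from a lattice of initial
    guesses (or caller-provided ones), deduplicated, and classified as
    stable when both Jacobian eigenvalues have negative real part.
    Non-converged guesses are dropped.
    """
    r_sur = config.surround_rate(surround)
    if guesses is None:
        ue = np.linspace(-72.0, -60.0, 13)
        ui = np.linspace(-72.0, -58.0, 15)
        guesses = [(a, b) for a in ue for b in ui]
    found: list[FixedPoint] = []
    for g0 in guesses:
        sol = root(lambda v: _drift(v[0], v[1], config, r_sur), g0, tol=tol)
        if not sol.success:
            continue
        u_E, u_I = sol.x
        res = float(np.max(np.abs(_drift(u_E, u_I, config, r_sur))))
        if res > 1e-8:
            continue
        if any(abs(f.u_E - u_E) < 1e-4 and abs(f.u_I - u_I) < 1e-4 for f in found):
            continue
        eig = np.linalg.eigvals(_jacobian(u_E, u_I, config))
        found.append(FixedPoint(u_E=float(u_E), u_I=float(u_I),
                                stable=bool(np.all(eig.real < 0)), residual=res))
    found.sort(key=lambda f: f.u_E)
    return found


def isn_diagnostics(fp: FixedPoint, config: MeanFieldConfig) -> dict:
    """Inhibition-stabilization test at a fixed point.

    The network is an ISN at the point if the excitatory subsystem with
    frozen inhibition is unstable (positive E-E Jacobian entry) while
    the full two-variable system is stable.
    """
    J = _jacobian(fp.u_E, fp.u_I, config)
    eig = np.linalg.eigvals(J)
    return {
        "e_only_unstable": bool(J[0, 0] > 0),
        "full_stable": bool(np.all(eig.real < 0)),
        "is_isn": bool(J[0, 0] > 0 and np.all(eig.real < 0)),
    }
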