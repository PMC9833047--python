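"""Up/down and global/local slow-wave stage classification.

A local network is labelled *up* when its mean excitatory membrane
potential has most recently crossed above the up-transition threshold
(-68.25 mV) and *down* once it falls below the down-transition threshold
(-69.75 mV); between the thresholds the previous label persists
(hysteresis). A state is *global* when at least two of the other three
local networks share it, *local* otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "THETA_UP",
    "THETA_DOWN",
    "classify_updown",
    "classify_global_local",
    "state_name",
    "state_names_grid",
    "state_firing_rates",
    "labels_to_intervals",
    "HysteresisClassifier",
]

THETA_UP = -68.25
THETA_DOWN = -69.75


def classify_updown(mean_trace, theta_up: float = THETA_UP,
                    theta_down: float = THETA_DOWN,
                    initial_up: bool = False) -> np.ndarray:
    """Hysteresis two-threshold up/down labelling of one membrane trace.

    Returns a boolean array (True = up). The prefix before the first
    crossing keeps the initial label (immaterial after burn-in discard).
    """
    if not theta_down < theta_up:
        raise ValueError("theta_down must lie below theta_up")
    trace = np.asarray(mean_trace, dtype=float)
    event = np.where(trace > theta_up, 1, np.where(trace < theta_down, 0, -1))
    event[0] = event[0] if event[0] >= 0 else (1 if initial_up else 0)
    idx = np.where(event >= 0, np.arange(len(event)), 0)
    np.maximum.accumulate(idx, out=idx)
    return event[idx].astype(bool)


def classify_global_local(up_labels: np.ndarray) -> np.ndarray:
    """Global/local annotation from the four networks' up/down labels.

    up_labels has shape (n_bins, 4) (True = up). A network's state is
    global iff at least two of the other three networks are in the same
    state at that bin. Returns a boolean array of the same shape
    (True = global).
    """
    up = np.asarray(up_labels, dtype=bool)
    if up.ndim != 2 or up.shape[1] != 4:
        raise ValueError("expected labels of shape (n_bins, 4)")
    n_up = up.sum(axis=1, keepdims=True)
    same_others = np.where(up, n_up - 1, (4 - n_up) - 1)
    return same_others >= 2


def state_name(is_up: bool, is_global: bool) -> str:
    return ("global-" if is_global else "local-") + ("up" if is_up else "down")


def state_names_grid(up_labels: np.ndarray, global_labels: np.ndarray) -> np.ndarray:
    """Elementwise state names from up/down and global/local boolean grids."""
    up = np.asarray(up_labels, dtype=bool)
    gl = np.asarray(global_labels, dtype=bool)
    out = np.where(up, np.where(gl, "global-up", "local-up"),
                   np.where(gl, "global-down", "local-down"))
    return out


def state_firing_rates(counts: np.ndarray, up_labels: np.ndarray,
                       global_labels: np.ndarray, n_neurons: int,
                       dt: float = 1.0) -> dict:
    """Mean per-neuron firing rate (Hz) of one population in each state.

    counts is the per-bin spike count of the population; labels refer to
    the same network. States never visited are reported as None (missing),
    not zero.
    """
    counts = np.asarray(counts)
    names = state_names_grid(up_labels, global_labels)
    rates: dict[str, float | None] = {}
    for state in ("global-down", "local-down", "global-up", "local-up"):
        sel = names == state
        t_in_state = sel.sum() * dt * 1e-3  # s
        if t_in_state == 0:
            rates[state] = None
        else:
            rates[state] = float(counts[sel].sum() / (t_in_state * n_neurons))
    return rates


def labels_to_intervals(up_labels: np.ndarray, global_labels: np.ndarray,
                        dt: float = 1.0) -> pd.DataFrame:
    """Serialize per-bin labels as an interval table.

    Columns: network, start_ms, end_ms, updown, scope. Consecutive bins
    with identical (updown, scope) are merged.
    """
    up = np.asarray(up_labels, dtype=bool)
    gl = np.asarray(global_labels, dtype=bool)
    rows = []
    for k in range(up.shape[1]):
        code = up[:, k].astype(int) * 2 + gl[:, k].astype(int)
        change = np.flatnonzero(np.diff(code)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(code)]])
        for s, e in zip(starts, ends):
            rows.append({
                "network": k,
                "start_ms": s * dt,
                "end_ms": e * dt,
                "updown": "up" if up[s, k] else "down",
                "scope": "global" if gl[s, k] else "local",
            })
    return pd.DataFrame(rows)


class HysteresisClassifier:
    """Online per-bin up/down + global/local classifier for n networks.

    Used by experiment drivers that must know the momentary sleep state
    (trial binning, reactivation gating) while the simulation runs.
    """

    def __init__(self, n_networks: int = 4, theta_up: float = THETA_UP,
                 theta_down: float = THETA_DOWN):
        if not theta_down < theta_up:
            raise ValueError("theta_down must lie below theta_up")
        self.theta_up = theta_up
        self.theta_down = theta_down
        self.up = np.zeros(n_networks, dtype=bool)  # initial label: down

    def update(self, mean_u: np.ndarray) -> list[str]:
        """Consume this bin's mean E potentials; return per-network state names."""
        self.up = np.where(mean_u > self.theta_up, True,
                           np.where(mean_u < self.theta_down, False, self.up))
        n_up = int(self.up.sum())
        n = len(self.up)
        names = []
        for k in range(n):
            same_others = (n_up - 1) if self.up[k] else (n - n_up - 1)
            names.append(state_name(bool(self.up[k]), same_others >= 2))
        return names
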