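"""Configuration, seeding, fixture generation and serialization.

Every run is a pure function of (config, seed): one root seed spawns
labelled child random streams so that adding instrumentation to one
component never perturbs another. Spike trains serialize as two-column
delimited text (source id, time in ms) for portability and as an .npz
container for large runs.
"""

from __future__ import annotations

import importlib.resources
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .network import NetworkConfig
from .params import (
    ActivationParams,
    AdaptationParams,
    KernelParams,
    PlasticityParams,
    RefractoryParams,
)
from .single_neuron import FeedforwardConfig

__all__ = [
    "RunConfig",
    "SpikeTrain",
    "generate_poisson_train",
    "load_config",
    "save_config",
    "validate_config",
    "config_objects",
    "labelled_rng",
    "save_spike_trains",
    "load_spike_trains",
]

_REQUIRED_FIELDS = {
    "simulation": ["dt", "burn_in", "burn_in_sleep", "initial_last_spike"],
    "activation": ["E", "I"],
    "refractory": ["tau_R"],
    "kernel": ["tau_m_E", "tau_m_I", "u_r"],
    "adaptation": ["tau_a", "beta"],
    "plasticity": ["alpha", "lam", "tau_C"],
    "single_neuron": ["n_stim", "n_background", "w_stim", "w_background",
                      "background_rate_up", "background_rate_down"],
    "network": ["n_E", "n_I", "n_local", "w_EE", "w_EI", "w_IE",
                "p_EE_long", "p_IE_long"],
    "classification": ["theta_up", "theta_down"],
    "sleep": ["n_G", "n_L", "w_init", "rate_start", "rate_end",
              "blocking_margin"],
}


@dataclass(frozen=True)
class RunConfig:
    """Run-level settings shared by all experiment drivers."""

    dt: float = 1.0
    burn_in: float = 10_000.0
    seed: int = 0
    scale: float = 1.0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


@dataclass
class SpikeTrain:
    """Spike times of one source on the simulation grid."""

    source: int
    times: np.ndarray  # ms, strictly increasing, multiples of dt
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if len(self.times) and not np.allclose(
                np.round(self.times / self.dt) * self.dt, self.times):
            raise ValueError("spike times must be multiples of the step size")


def generate_poisson_train(rate: float, duration: float, dt: float,
                           rng: np.random.Generator, source: int = 0) -> SpikeTrain:
    """Homogeneous Poisson spike train on the discrete grid.

    Per bin the spike probability is 1 - exp(-rate*dt), so the empirical
    rate is unbiased at any dt.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n_bins = int(round(duration / dt))
    p = -np.expm1(-rate * 1e-3 * dt)
    spikes = rng.random(n_bins) < p
    return SpikeTrain(source=source, times=np.flatnonzero(spikes) * dt, dt=dt)


def labelled_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic child random stream for a named component."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _default_config_text() -> str:
    return importlib.resources.files("infomaxstdp").joinpath(
        "data/default.yaml").read_text()


def validate_config(cfg: dict) -> None:
    """Check that every required parameter is present; name the missing one."""
    for section, fields in _REQUIRED_FIELDS.items():
        if section not in cfg:
            raise ValueError(f"config missing section {section!r}")
        for f in fields:
            if f not in cfg[section]:
                raise ValueError(f"config missing field {section}.{f}")
    for tag in ("E", "I"):
        for f in ("r0", "u0", "delta_u"):
            if f not in cfg["activation"][tag]:
                raise ValueError(f"config missing field activation.{tag}.{f}")


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a config file; None loads the packaged defaults."""
    text = Path(path).read_text() if path is not None else _default_config_text()
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    validate_config(cfg)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def config_objects(cfg: dict) -> dict:
    """Build the typed parameter objects from a validated config dict."""
    act_E = ActivationParams(population_tag="E", **cfg["activation"]["E"])
    act_I = ActivationParams(population_tag="I", **cfg["activation"]["I"])
    kernel = KernelParams(**cfg["kernel"])
    refractory = RefractoryParams(**cfg["refractory"])
    adaptation = AdaptationParams(**cfg["adaptation"])
    plasticity = PlasticityParams(**cfg["plasticity"])
    feedforward = FeedforwardConfig(act=act_E, kernel=kernel,
                                    refractory=refractory,
                                    **cfg["single_neuron"])
    network = NetworkConfig(act_E=act_E, act_I=act_I, kernel=kernel,
                            adaptation=adaptation, refractory=refractory,
                            dt=cfg["simulation"]["dt"], **cfg["network"])
    return {
        "act_E": act_E, "act_I": act_I, "kernel": kernel,
        "refractory": refractory, "adaptation": adaptation,
        "plasticity": plasticity, "feedforward": feedforward,
        "network": network, "raw": cfg,
    }


def save_spike_trains(trains: list[SpikeTrain], path: str | Path,
                      binary: bool = False) -> None:
    """Write spike trains as two-column text (source, time) or .npz."""
    path = Path(path)
    if binary:
        np.savez_compressed(
            path,
            sources=np.concatenate([np.full(len(t.times), t.source) for t in trains]),
            times=np.concatenate([t.times for t in trains]),
            dt=np.array([trains[0].dt if trains else 1.0]))
        return
    with open(path, "w") as fh:
        fh.write("# source\ttime_ms\n")
        for t in trains:
            for time in t.times:
                fh.write(f"{t.source}\t{time:.3f}\n")


def load_spike_trains(path: str | Path, dt: float = 1.0) -> list[SpikeTrain]:
    """Read spike trains written by :func:`save_spike_trains`."""
    path = Path(path)
    if path.suffix == ".npz":
        data = np.load(path)
        sources, times = data["sources"], data["times"]
        dt = float(data["dt"][0])
    else:
        raw = np.loadtxt(path, comments="#", ndmin=2)
        if raw.size == 0:
            return []
        sources, times = raw[:, 0], raw[:, 1]
    out = []
    for s in np.unique(sources):
        out.append(SpikeTrain(source=int(s), times=np.sort(times[sources == s]),
                              dt=dt))
    return out
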