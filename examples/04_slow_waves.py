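"""Global and local slow waves in the four-network model.

Simulates the 800E + 200I network for a minute, classifies each local
network's up/down states by hysteresis thresholds (-68.25 / -69.75 mV)
and each state as global or local (shared by at least two of the other
three networks). Excitatory firing rates order as
global down < local down < global up < local up.
"""

import numpy as np

from infomaxstdp import NetworkConfig, simulate
from infomaxstdp.states import (classify_global_local, classify_updown,
                                state_firing_rates)

res = simulate(NetworkConfig(), duration=60_000,
               rng=np.random.default_rng(3), burn_in=10_000)
up = np.column_stack([classify_updown(res.mean_u_E[:, k]) for k in range(4)])
gl = classify_global_local(up)

rates = state_firing_rates(res.e_counts[:, 0], up[:, 0], gl[:, 0], n_neurons=200)
print("E1 firing rate by sleep state (Hz):")
for state, rate in rates.items():
    print(f"  {state:12s} {rate:6.2f}")

i_down = res.i_counts[~up[:, 0], 0].mean() * 1000 / 50
i_up = res.i_counts[up[:, 0], 0].mean() * 1000 / 50
print(f"\nI1 rate: {i_down:.2f} Hz in down states vs {i_up:.2f} Hz in up states")
print("Inhibition is nearly silent in down states (high threshold) and"
      "\nstabilizes the recurrent excitation in up states.")
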