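"""State-dependent plasticity inside the slow-wave network.

Pre-only stimulation of feedforward synapses onto a random E1 neuron,
with each trial binned by the sleep state at stimulation time. In the
weak-many condition (40 synapses at 0.09 mV) the information term can
beat the cost even in up states: global up states potentiate while
local up states — with their higher baseline rates — depress.

Run time is a few minutes (several hundred trials inside the running
network); lower n_trials for a quick look.
"""

import numpy as np

from infomaxstdp import NetworkConfig, PlasticityParams, run_network_stdp

res = run_network_stdp(NetworkConfig(), "WM", [None], PlasticityParams(),
                       np.random.default_rng(11), n_trials=1000)
print("WM condition, pre-only stimulation:")
print("  state         mean_dw_mV      sem      n")
for state in ("global-down", "local-down", "global-up", "local-up"):
    r = res.results[(state, None)]
    print(f"  {state:12s} {r['mean']:10.6f}  {r['sem']:8.6f}  {r['n']:4d}")
print("\nWeight changes descend global down > local down > global up >"
      "\nlocal up, mirroring the ascending baseline firing rates.")
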