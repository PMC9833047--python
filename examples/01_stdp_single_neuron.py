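"""STDP windows of the infomax rule in the up and down states.

Calibrates the mean activation intensity of each state from a long
background-only run, then measures the mean weight change of the 20
stimulated synapses for several pairing offsets. The down-state curve
sits above the up-state curve at every offset: at a low background
intensity a postsynaptic spike carries more information, so the same
pairing potentiates more (or depresses less).
"""

import numpy as np

from infomaxstdp import (FeedforwardConfig, PlasticityParams,
                         estimate_mean_intensity, measure_stdp_curve)

config = FeedforwardConfig()
plasticity = PlasticityParams()
offsets = [-50.0, -10.0, 10.0, 50.0]

for state in ("down", "up"):
    rng = np.random.default_rng(1)
    g_bar = estimate_mean_intensity(config, state, rng, duration=3e5).g_bar
    curve = measure_stdp_curve(config, offsets, plasticity, state, rng,
                               n_trials=1500, g_bar=g_bar)
    print(f"\n{state} state (mean intensity {g_bar:.2f} Hz)")
    print("  offset_ms  mean_dw_mV      sem")
    for off, m, s in zip(curve.offsets, curve.mean_dw, curve.sem_dw):
        print(f"  {off:9.0f}  {m:10.5f}  {s:7.5f}")
    print(f"  pre-only   {curve.pre_only_mean:10.5f}  {curve.pre_only_sem:7.5f}")

print("\nPositive offsets (pre-post) potentiate in the down state and are"
      "\npulled toward depression in the up state; negative offsets"
      "\n(post-pre) depress in both states because refractoriness blocks"
      "\nthe information term while the weight cost still applies.")
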