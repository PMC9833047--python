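"""Memory consolidation and forgetting during simulated NREM sleep.

Two presynaptic populations project onto a task neuron: G reactivates
during global up states, L during local up states (synchronized Poisson
events decaying from 7.5 to 5.0 Hz over the session). Under the infomax
rule G potentiates and L depresses; blocking plasticity during one
state freezes the corresponding population. Sessions here are scaled to
one fifth of the full length; expect a few minutes of run time.
"""

from infomaxstdp import NetworkConfig, PlasticityParams, run_sleep_experiment

res = run_sleep_experiment(NetworkConfig(), PlasticityParams(), seed=9,
                           n_trials=3, scale=0.2,
                           probe_kwargs=dict(n_probes=60))
print("condition            dG_mV     dL_mV     dsum_mV   dperf_Hz")
for mode, r in res.items():
    print(f"{mode:20s} {r['dw_G']:+.4f}   {r['dw_L']:+.4f}   "
          f"{r['dsum']:+.4f}   {r['dperf']:+.3f}")
print("\nSummed weights and task performance order as"
      "\nglobal-up-blocked < control < local-up-blocked: global slow"
      "\nwaves consolidate the reactivated memory, local ones erode it.")
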