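"""Calibrating the synaptic cost coefficient lambda.

Pre-only stimulation in the down state should, on average, leave the
stimulated weights unchanged; the cost coefficient is root-found so that
the information-term potentiation and the per-spike cost -lambda*w
cancel. The calibrated value sits near 0.32 per mV^2, the default used
throughout the package.
"""

from infomaxstdp import FeedforwardConfig, PlasticityParams, calibrate_lambda

lam = calibrate_lambda(FeedforwardConfig(), PlasticityParams(), seed=7,
                       n_trials=10_000)
print(f"calibrated lambda = {lam:.4f}  (1/mV^2)")
print("Mean pre-only down-state weight change is zero at this lambda;"
      "\nlarger lambda turns the same stimulation into net depression.")
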