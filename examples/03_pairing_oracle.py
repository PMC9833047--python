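"""Analytic pairing formula versus the simulated information term.

For one pre-post pairing against a constant baseline potential the
information-term weight change has the closed form
g'(u0+du) * log(1 + dg/g_bar) / (g_bar + dg). A stripped-down
deterministic simulation (hard refractory window, no spontaneous
spikes, dt = 0.1 ms) reproduces it to within a few percent.
"""

from infomaxstdp import stdp_closed_form, simulate_pairing_information_term
from infomaxstdp.params import E_ACTIVATION

print("baseline_mV  step_mV  closed_form  simulated   rel_err")
for u0, du in [(-69.9, 2.0), (-69.9, 10.0), (-68.5, 5.0)]:
    ana = stdp_closed_form(u0, du, E_ACTIVATION)
    sim = simulate_pairing_information_term(u0, du, dt=0.1)
    print(f"{u0:11.1f}  {du:7.1f}  {ana:11.5f}  {sim:9.5f}  {sim/ana-1:+8.2%}")

print("\nThe value (in 1/mV, times the learning rate alpha for mV) falls"
      "\nas the baseline intensity g_bar rises: the depression bias of"
      "\nhigh firing rates.")
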