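"""Mean-field phase plane of one local network.

Reduces a local network to two membrane variables (u_E, u_I) and finds
the stable intersections of the nullclines under down-state and
up-state surround drive. The four stable potentials reproduce the
ordering global down < local down < global up < local up, and both up
states are inhibition-stabilized: the excitatory subsystem alone is
unstable and feedback inhibition holds it in place, which is why
surround excitation *lowers* the up-state potential.
"""

from infomaxstdp import MeanFieldConfig, NetworkConfig, find_fixed_points
from infomaxstdp.meanfield import isn_diagnostics

mf = MeanFieldConfig.from_network(NetworkConfig())
points = {}
for surround in ("down", "up"):
    fps = [f for f in find_fixed_points(mf, surround) if f.stable]
    lo, hi = min(fps, key=lambda f: f.u_E), max(fps, key=lambda f: f.u_E)
    if surround == "down":
        points["global-down"], points["local-up"] = lo, hi
    else:
        points["local-down"], points["global-up"] = lo, hi

print("state         u_E_mV    u_I_mV   rate_E_Hz  ISN")
for name in ("global-down", "local-down", "global-up", "local-up"):
    f = points[name]
    isn = isn_diagnostics(f, mf)["is_isn"]
    print(f"{name:12s} {f.u_E:8.2f}  {f.u_I:8.2f}  {f.rate_E:8.2f}  {isn}")
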