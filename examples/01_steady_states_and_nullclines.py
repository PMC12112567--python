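"""Steady states of the silencing/copy-number ODEs from their nullclines.

Loads the calibrated wild-type ("reference") and bistable presets, finds
the intersections of the M and CN nullclines under the quasi-steady-state
RNA reduction, and prints each fixed point with its stability and branch.
"""
from hsatdyn import find_steady_states, get_preset

for name in ("reference", "bistable"):
    p = get_preset(name)
    print(f"\n{name} preset (phi = {p.phi:.4g}):")
    for s in find_steady_states(p):
        st = s.state
        label = "stable  " if s.stable else "unstable"
        print(f"  x1={st.x1:9.3f}  x2={st.x2:9.3f}  x3={st.x3:9.3f}  "
              f"{label}  {s.branch}  (methylated fraction "
              f"{st.methylated_fraction if st.x3 else float('nan'):.3f})")

# The reference set has one silenced attractor besides the (unstable)
# origin; the bistable set adds a desilenced attractor with ~6x the copy
# number, separated by a saddle: two cell states with different repeat
# counts can coexist at identical rate constants.
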