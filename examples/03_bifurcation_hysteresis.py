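"""Bifurcation diagram and hysteresis in the cooperative methylation rate.

Sweeps phi downward from the wild-type value: the system passes from
silenced monostability through a bistable window into desilenced
monostability, and a continuation there shows a hysteresis loop.
"""
import numpy as np

from hsatdyn import get_preset, hysteresis_scan, sweep_parameter

p = get_preset("reference")
grid = np.logspace(np.log10(0.01 * p.phi), np.log10(p.phi), 20)
result = sweep_parameter(p, "phi", grid)
for v, regime in zip(result.grid, result.regimes):
    print(f"phi={v:8.4f}  {regime}")

res = hysteresis_scan(p, "phi", grid)
gaps = res.loop_gap()
print(f"\nhysteresis: max forward/backward separation {gaps.max():.3f} "
      f"(inside the window), {gaps[0]:.2e} / {gaps[-1]:.2e} at the ends")
# A nonzero gap only inside the bistable window is the hysteresis loop:
# which branch the system sits on depends on the sweep direction.
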