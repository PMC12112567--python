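"""One- and two-parameter regime maps around the reference set.

Each parameter is varied on a normalized log grid (1 = reference value)
and the regime at every point is classified by multi-start integration.
"""
from hsatdyn import get_preset, scan_1d, scan_2d

p = get_preset("reference")
for name in ("phi", "mu", "kappa4"):
    rm = scan_1d(p, name, (1e-2, 1e2), 13)
    runs = ", ".join(f"{r}:[{a:.3g},{b:.3g}]" for r, a, b in rm.intervals())
    print(f"{name:7s} {runs}")

rm = scan_2d(p, "phi", "mu", (1e-1, 1e1), (1e-1, 1e1), 5, 5)
print("\nphi (rows, up) x mu (cols, right):")
for row in rm.regimes[::-1]:
    print("  " + " ".join(f"{str(r)[:4]:4}" for r in row))
# phi and mu act antagonistically: the silenced region retreats to higher
# phi as mu grows.  kappa4 alone shows no bistable range.
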