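# hsatdyn

Dynamics of pericentromeric satellite repeat silencing and copy number.

Human pericentromeric satellite arrays (HSATII and relatives) are tandem
DNA repeats kept silent by heterochromatin marks. Their transcripts can be
reverse-transcribed back into the array, so copy number, methylation state
and RNA level form a feedback loop: hypomethylated arrays transcribe more,
insert more copies, and dilute silencing further — a circuit implicated in
the dramatic satellite expansions seen in many cancers. `hsatdyn`
implements a quantitative model of this loop for researchers in chromatin
biology and systems biology who want to explore which silencing reactions
control repeat copy number.

## The model

Three coupled ODEs track the lncRNA level `x1`, the methylated repeat
count `x2` (= M), and the total copy number `x3` (= CN; unmethylated
copies are U = x3 − x2):

    dx1/dt = α·x3 / (1 + x2/κ1) − δ·x1
    dx2/dt = φ·[(x2/κ2)/(1 + x2/κ2)]·x2·(x3 − x2) + η·(x3 − x2) − μ·x2
    dx3/dt = σ·x1 / (1 + x2/κ3) − γ·x3² / (1 + x2/κ4)

Transcription (α) is proportional to copy number and repressed by
methylation; U copies methylate spontaneously (η) or cooperatively (φ,
saturating in M); M demethylates (μ); transcripts insert new copies by
reverse transcription (σ) and copies are lost to recombination (γ), both
repressed by methylation. Rates are per generation; κ's are repression /
saturation scales in copies.

Because RNA equilibrates much faster than chromatin or copy number, a
quasi-steady-state reduction `x1* = α·x3/(δ(1 + x2/κ1))` collapses the
system to the (x2, x3) plane, where the M nullcline (dx2 = 0) and the CN
nullcline (dx3 = 0) intersect at the steady states. For μ ≫ η the M
nullcline is folded, and depending on where the CN nullcline passes the
system is monostably silenced, monostably desilenced, or **bistable**: a
silenced low-copy state and a desilenced high-copy state coexist, with
saddle-node bifurcations and hysteresis as rates vary.

A companion **spatial model** represents the array as a 1D chain of U/M
monomers: cooperative methylation acts only within two repeats, insertion
places new U monomers next to transcribing U sites, recombination deletes
U sites, and "silenced domains" (M runs merged across gaps of up to 20% U)
emerge as the unit of copy-number regulation.

The paper-style reference rate constants are not hard-coded: a calibration
routine (`hsatdyn.calibrate`) constructs them from the nullcline fold
geometry and verifies the regime structure; its output ships as the
`reference` and `bistable` presets.

## Worked example

```python
from hsatdyn import find_steady_states, get_preset

for name in ("reference", "bistable"):
    p = get_preset(name)
    print(name, p.phi)
    for s in find_steady_states(p):
        print(s.state, s.stable, s.branch)
```

Running `python examples/01_steady_states_and_nullclines.py` prints:

```
reference preset (phi = 0.5):
  x1=    0.000  x2=    0.000  x3=    0.000  unstable  desilenced  (methylated fraction nan)
  x1=   34.229  x2=   89.150  x3=   95.258  stable    silenced  (methylated fraction 0.936)

bistable preset (phi = 0.07339):
  x1=    0.000  x2=    0.000  x3=    0.000  unstable  desilenced  (methylated fraction nan)
  x1=  703.074  x2=    0.660  x3=  712.361  stable    desilenced  (methylated fraction 0.001)
  x1=  542.544  x2=    5.240  x3=  599.407  unstable  desilenced  (methylated fraction 0.009)
  x1=   50.166  x2=   72.434  x3=  122.841  stable    silenced  (methylated fraction 0.590)
```

The wild-type reference set has a single silenced attractor (94% of copies
methylated, ~95 copies). Lowering the cooperative methylation rate into
the bistable window adds a desilenced attractor with ~6× the copy number
and almost no methylation, separated by a saddle: genetically identical
cells can sit at very different repeat counts, and a small rate change can
flip them. The other scripts under `examples/` walk through trajectories,
the bifurcation diagram with its hysteresis loop, 1D/2D sensitivity maps,
and the spatial chain.

A thin CLI mirrors the library:

```
hsatdyn simulate   --preset reference --out out_sim
hsatdyn nullclines --preset bistable  --out out_nc
hsatdyn bifurcation --param phi --from 0.005 --to 0.5 --points 60 --out out_bif
hsatdyn spatial    --length 15000 --generations 100 --seed 1 --out out_sp
hsatdyn calibrate  --out out_cal
```

Each output directory carries a `sidecar.json` with the full resolved
configuration, so every result is reproducible from its sidecar alone.

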