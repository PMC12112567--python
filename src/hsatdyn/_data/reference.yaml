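# Wild-type reference parameter set, produced and verified by
# hsatdyn.calibrate.calibrate_reference_parameters() (seed 0, template
# accepted on the first candidate).  Monostably silenced; see the
# calibration module for the constraints this set satisfies.
alpha: 2.0
delta: 2.0
phi: 0.5
eta: 0.0002
mu: 0.25
sigma: 1.0
gamma: 0.001367511119786266
kappa1: 50.0
kappa2: 1000.0
kappa3: 50.0
kappa4: 10000.0
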