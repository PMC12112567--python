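# Reference set with the cooperative methylation rate phi moved to the
# geometric middle of the verified bistable window of the phi sweep
# (calibrate_reference_parameters().bistable_phi).  Three interior steady
# states: stable desilenced, saddle, stable silenced.
alpha: 2.0
delta: 2.0
phi: 0.07338996338110347
eta: 0.0002
mu: 0.25
sigma: 1.0
gamma: 0.001367511119786266
kappa1: 50.0
kappa2: 1000.0
kappa3: 50.0
kappa4: 10000.0
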