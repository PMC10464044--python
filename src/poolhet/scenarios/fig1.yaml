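# Heterogeneity-detection power study: 100 subjects per arm, true response
# rate 50% in the SAT and rwCC1; rwCC2 varies.
n_sat: 100
n_rwcc: 100
rr_sat: 0.5
rr_rwcc1: 0.5
rr_rwcc2_grid: [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
replicates: 1000
bootstrap_B: 1000
alpha: 0.05
seed: 1
effect_measure: risk_difference
ipd_method: wald
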