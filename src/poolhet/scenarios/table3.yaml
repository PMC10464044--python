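# Test-then-pool operating characteristics, effective-treatment scenario:
# true SAT response rate 80%, rwCC1 50%; rwCC2 biased upward.
n_sat: 50
n_rwcc_each: 25
rr_sat: 0.8
rr_rwcc1: 0.5
rr_rwcc2_grid: [0.5, 0.6, 0.7, 0.8]
het_alpha: 0.10
comparison_alpha: 0.05
het_method: fisher_exact
comparison_test: fisher
replicates: 1000000
seed: 1
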