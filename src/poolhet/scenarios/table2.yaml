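# Test-then-pool operating characteristics, null scenario:
# true SAT and rwCC1 response rates 50%; rwCC2 biased downward.
n_sat: 50
n_rwcc_each: 25
rr_sat: 0.5
rr_rwcc1: 0.5
rr_rwcc2_grid: [0.5, 0.4, 0.3, 0.2]
het_alpha: 0.10
comparison_alpha: 0.05
het_method: fisher_exact
comparison_test: fisher
replicates: 100000
seed: 1
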