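name: stress
n_coding: 3000
n_lnc: 3036
n_planted: 36
window_bp: 100000
planted_log2fc: 2.0
base_mean: 300.0
dispersion: 0.1
n_reps: 3
conserved_decoy_frac: 0.2
single_side_decoy_frac: 0.1
ortholog_noise: 0.02
second_step_prob: 0.3
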