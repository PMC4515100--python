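name: linear_strong_mcar_monotone
model: linear_strong
mechanism: monotone_mcar
n: 708
reps: 1000
m: 5
m2: 5
correlation: 0.2
iterations: 10
donors: 5
coef_mode: imputation_specific
seed: 0
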