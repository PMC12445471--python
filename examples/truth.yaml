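# inside-out + hierarchy ground truth for `cortexdev simulate`
n_parcels: 30
depth_bins: [1, 2, 3, 4, 5]
baseline: 1.2
amplitude_fast: 0.5
amplitude_slow: 0.45
rate_fast: 0.18
rate_slow: 0.02
onset: 5.0
sigma: 0.03
sigma_b: 0.0
beta_sex: 0.02
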