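# macaque-like longitudinal design: 33 subjects at 5 timepoints, one with 4
mode: longitudinal
n_subjects: 33
timepoints: 5
n_short_subjects: 1
age_min: 0.0833
age_max: 3.0
sex_ratio: 0.5
species: macaque
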