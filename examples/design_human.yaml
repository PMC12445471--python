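# human-like cross-sectional design
mode: cross_sectional
n_subjects: 200
age_min: 5.5
age_max: 36.0
sex_ratio: 0.5
species: human
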