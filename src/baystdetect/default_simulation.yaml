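n_areas: 211
grid: null
n_times: 8
alpha0: 0.0
sigma_v: 0.3
sigma_h: 0.15
sigma_gamma: 0.05
seasonal_amplitude: 0.4
peak_time: 4
frac_unusual: 0.0
unusual_areas: []
deviation_shape: flat
deviation_magnitude: 0.7
spike_time: null
shift_offset: 2
expected_range:
- 100.0
- 500.0
covariate_effects: {}
persons_per_area: 50000.0
seed: 0
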