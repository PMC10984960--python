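# Synthetic cohort mirroring the reference study conditions,
# at desk scale (see docs/methods.md for parameter meanings).
n_subjects: 118
grid_shape: [24, 28, 24]
n_sources: 5
ab_positive_fraction: 0.3813559322033898   # 45 / 118
loading_shift: 1.24      # population r(disc loading, Ab) ~ -0.52
age_loading_r: -0.556
noise_sd: 0.5
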