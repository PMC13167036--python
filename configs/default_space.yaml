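# Default search space for tuning the generator to real reference frames.
# Bounds are engineering choices (the tunable subset and its ranges are
# deliberately explicit config, not code constants); noise amplitudes use
# log scale because plausible values span orders of magnitude.
background: {low: 0.2, high: 0.8, scale: linear}
contrast: {low: -0.8, high: 0.8, scale: linear}
psf_sigma: {low: 0.5, high: 3.0, scale: log}
count_mean: {low: 1.0, high: 40.0, scale: linear}
count_sd: {low: 0.5, high: 15.0, scale: linear}
fil_len_mean: {low: 30.0, high: 400.0, scale: log}
fil_len_sd: {low: 5.0, high: 200.0, scale: log}
bend_shape: {low: 0.5, high: 5.0, scale: linear}
bend_scale: {low: 0.001, high: 0.2, scale: log}
flip_prob: {low: 0.0, high: 0.5, scale: linear}
noise_gauss_sd: {low: 0.001, high: 0.1, scale: log}
photon_scale: {low: 20.0, high: 2000.0, scale: log}
speckle_sd: {low: 0.001, high: 0.2, scale: log}
vignette_strength: {low: 0.0, high: 0.5, scale: linear}
blur_sigma: {low: 0.0, high: 2.0, scale: linear}
bgfield_amp: {low: 0.0, high: 0.3, scale: linear}
bgfield_scale: {low: 5.0, high: 100.0, scale: log}
n_spots_mean: {low: 0.0, high: 15.0, scale: linear}
seed_len: {low: 0.0, high: 30.0, scale: linear}
seed_gain: {low: 0.0, high: 0.6, scale: linear}
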