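simulate:
  n_nodes: 12
  n_per_group: [10, 10]
  effect_size: 5.0
  subject_noise_sd: 0.01
  n_planted: 4
  n_cross_hemisphere_planted: 2
  seed: 7
train:
  n_seeds: 2
  epochs: 30
saliency:
  top_k_nodes: 5
  top_k_edges: 5
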