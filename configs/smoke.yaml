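# Desk-scale smoke profile: exercises the full pipeline in about a minute.
n_genes: 200
n_test_genes: 40
seed: 1
simulation:
  root_length_min: 100
  root_length_max: 150
training:
  conv_filters: [8, 8, 8, 8, 8, 8, 8]
  dense_width: 16
  dropout: 0.1
  batch_size: 32
  epochs: 2
  validation_fraction: 0.1
evaluation:
  threshold: 0.5
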