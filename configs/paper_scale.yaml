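# Full-scale training profile: the study-scale conditions (1,000,000 genes,
# 50 epochs, batch 512, baseline simulation parameters).  Documented as a
# named preset; expect GPU-scale resources if run end to end.
n_genes: 1000000
n_test_genes: 2000
seed: 0
simulation:
  n_taxa: 8
  divergence: 0.2
  indel_rate: 0.1
training:
  conv_filters: [32, 32, 64, 64, 128, 128, 256]
  dense_width: 64
  dropout: 0.5
  learning_rate: 0.001
  batch_size: 512
  epochs: 50
  validation_fraction: 0.05
evaluation:
  threshold: 0.5
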