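# Scaled study settings: the reduced architecture and training protocol used
# by the packaged synthetic validation study (see docs/methods.md).
band_decimate: 10
model:
  feature_dim: 32
  patch_len: 250
  embed_dim: 32
  n_heads: 2
  encoder_depth: 1
  cnn_channels: [4, 8]
  classifier_hidden: 32
train:
  learning_rate: 0.003
  max_epochs: 15
  batch_size: 16
  k_folds: 3
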