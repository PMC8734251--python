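# Desk-scale training configuration for 32^3 phantom volumes.
learning_rate: 1.0e-3
final_learning_rate: 3.0e-4
max_steps: 300
network:
  base_channels: 4
  patch_shape: [32, 32, 32]
  n_encoder_stages: 3
  agf_radius: 2
  dropout_rate: 0.0
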