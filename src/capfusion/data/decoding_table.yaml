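# Decoding table for the 15-bit architecture genome.
# Bit fields are listed most-significant bit first; multi-bit fields index
# into their option list by the binary value of the field.
# The all-zero channel mask (no channel selected) is invalid: 7/8 of the
# 2^15 bit patterns decode, giving 28,672 distinct configurations.
bit_fields:
  - name: channel_mask
    bits: [0, 1, 2]        # one inclusion bit per channel, in channel order
  - name: time_steps
    bits: [3, 4]
  - name: n_recurrent_layers
    bits: [5]
  - name: recurrent_type
    bits: [6]
  - name: hidden_units
    bits: [7, 8]
  - name: dropout
    bits: [9, 10]
  - name: dense_size
    bits: [11, 12]
  - name: dense_activation
    bits: [13, 14]
options:
  channel_names: ["Fp2-F4", "F4-C4", "C4-A1"]
  time_steps: [5, 10, 15, 25]
  n_recurrent_layers: [1, 2]
  recurrent_type: ["unidirectional", "bidirectional"]
  hidden_units: [50, 100, 150, 200]
  dropout: [0.05, 0.10, 0.15, 0.20]
  dense_size: [0, 100, 200, 300]
  dense_activation: ["tanh", "sigmoid", "relu", "selu"]
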