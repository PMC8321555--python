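# 20 depressing (VCN-like) inputs at the ~180 Hz rate paradigm,
# six parameter-jittered model instances.
experiment:
  n_inputs: 20
  rate_paradigm: high
  plasticity: depressing
  n_instances: 6
  seed: 1
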