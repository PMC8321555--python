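# Combined-pathway paradigm: 20 facilitating (IC-like) inputs at ~110 Hz
# plus 20 depressing (VCN-like) inputs at ~180 Hz.  The two pathways use
# different rate paradigms so they are not artificially synchronized.
experiment:
  n_inputs: 20
  rate_paradigm: mid
  plasticity: facilitating
  n_instances: 6
  seed: 1
  combine_with:
    n_inputs: 20
    rate_paradigm: high
    plasticity: depressing
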