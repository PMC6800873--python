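# Erlang(0.5, 4) dwell time in X, absorbing recipient Y.
schema_version: 1
model:
  kind: erlang_chain
  rate: 0.5
  shape: 4
  recipients:
    - label: Y
      dwell: {type: sink}
simulation:
  horizon: 30.0
  grid: 301
  rtol: 1.0e-8
  atol: 1.0e-10
  seed: 7
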