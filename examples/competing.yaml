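# Competing dwell: min of Erlang(1, 2) and Erlang(2, 2); the winning
# process decides the recipient (Y1 vs Y2), each with exponential dwell.
schema_version: 1
model:
  kind: competing
  inflow: 1.0
  components:
    - {rate: 1.0, shape: 2}
    - {rate: 2.0, shape: 2}
  routing:
    - [1.0, 0.0]
    - [0.0, 1.0]
  recipients:
    - label: Y1
      dwell: {type: exponential, rate: 0.5}
    - label: Y2
      dwell: {type: exponential, rate: 0.5}
simulation:
  horizon: 12.0
  grid: 241
  seed: 3
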