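description: Free-latching single network with only slow inhibition; sweep the pattern
  load p across the no-latching / finite / infinite regimes.
buffer_network:
  N: 1000
  C_m: 150
  p: 200
  S: 5
  a: 0.25
  beta: 11.0
  U: 0.1
  w: 0.8
  tau1: 3.33
  tau2_fast: 100.0
  tau2_slow: 100.0
  gamma2_fast: 1.0
  tau_A: 2.0
  gamma_A: 0.0
  tau_B: 1.0e+6
  dynamic_threshold: false
  dt: 0.5
protocol:
  cue_strength: 4.0
  cue_duration: 100
  T_max: 500
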