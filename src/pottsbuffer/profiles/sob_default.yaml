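description: Mixed sign/word buffer; three unit clusters with cluster-wise dynamic threshold,
  heterogeneous adaptation (gamma2_fast map and random timescales).
lexicon_network:
  N: 600
  C_m: 90
  p: 200
  S: 7
  a: 0.25
  beta: 12.5
  U: 0.1
  w: 0.45
  tau1: 3.33
  tau2_fast: 33.3
  tau2_slow: 33.3
  gamma2_fast: 1.0
  tau_A: 2.0
  gamma_A: 0.0
  tau_B: 106.0
  dynamic_threshold: false
  dt: 0.5
buffer_network:
  N: 201
  C_m: 150
  p: 200
  S: 7
  a: 0.25
  beta: 12.5
  U: 0.1
  w: 0.5
  tau1: 3.33
  tau2_fast: 11.1
  tau2_slow: 33.3
  gamma2_fast: 0.5
  tau_A: 2.0
  gamma_A: 0.3
  tau_B: 106.0
  dynamic_threshold: true
  a_U: 0.5
  dt: 0.5
coupling:
  C_m_het: 150
  lambda_word: 0.55
  lambda_sign: 1.4
  interaction_mode: sigma_sigma
lexicon:
  n_signs: 25
  n_words: 25
  n_syllables: 15
  n_gesture_elements: 15
  n_clusters: 3
  a_word: 0.2537313432835821
  a_sign: 0.4626865671641791
  kind: mixed
protocol:
  cue_strength: 4.0
  cue_duration: 100
  T_max: 500
  n_batches: 1
  theta_on: 0.5
  theta_off: 0.35
  d_min: 10
  early_stop: true
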