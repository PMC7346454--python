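# Scenarios (iv) and (v): missingness depends on the exposure itself
# (beta_A), possibly also on the confounder (beta_U); no confounding of
# the exposure (alpha_U = 0).
figure: 5
u_observed: false
fixed:
  pi_U: 0.5
  alpha_U: 0.0
  sigma_A: 1.0
  gamma_A: 1.0
  gamma_U: 1.0
  gamma_UA: 0.0
  sigma_Y: 1.0
  beta_UA: 0.0
  target_p_missing: 0.5
  n: 10000
rows:
  parameter: beta_U
  values: [1.0, 0.5, 0.1, 0.0, -1.0]
axis:
  parameter: beta_A
  values: [0.0, 0.1, 0.5, 1.0]
scenarios: [i, ii, iv, v]
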