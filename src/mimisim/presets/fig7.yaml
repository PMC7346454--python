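# Scenario (vi), the unconstrained case: unmeasured confounding
# (alpha_U = 0.5), an outcome interaction (gamma_UA = 0.5), and missingness
# depending on both the exposure and the confounder.
figure: 7
u_observed: false
fixed:
  pi_U: 0.5
  alpha_U: 0.5
  sigma_A: 1.0
  gamma_A: 1.0
  gamma_U: 1.0
  gamma_UA: 0.5
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
scenarios: [iii, vi]
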