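# Scenarios (i)-(iii) with an exposure-confounder interaction in the
# outcome model (gamma_UA = 0.5): marginal and conditional causal effects
# differ (1.25 vs 1 and 1.5).
figure: 3
u_observed: false
fixed:
  pi_U: 0.5
  sigma_A: 1.0
  gamma_A: 1.0
  gamma_U: 1.0
  gamma_UA: 0.5
  sigma_Y: 1.0
  beta_A: 0.0
  beta_UA: 0.0
  target_p_missing: 0.5
  n: 10000
rows:
  parameter: beta_U
  values: [deterministic, 1.0, 0.5, 0.1, 0.0, -1.0]
axis:
  parameter: alpha_U
  values: [0.0, 0.1, 0.5, 1.0]
scenarios: [i, ii, iii, vi]
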