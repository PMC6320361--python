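# Kinetic constants of the six-gene Arabidopsis flowering network model,
# as estimated from experimental expression data in the literature.
# Units: beta in nM/min, K in nM, d in 1/min, delta in days; n dimensionless.
units:
  beta: nM/min
  K: nM
  d: 1/min
  delta: day
  n: dimensionless
values:
  beta1: 99.8
  beta2: 5.0
  beta3: 10.0
  beta4: 22.0
  beta5: 2.4
  beta6: 0.79
  beta7: 64.0
  beta8: 0.52
  beta9: 189.0
  beta10: 8.5
  beta11: 100.0
  beta12: 51.0
  K1: 9.82
  K2: 700.0
  K3: 10.1
  K4: 346.0
  K5: 842.0
  K6: 1011.0
  K7: 695.0
  K8: 1182.0
  K9: 2.4
  K10: 4.8
  K11: 909.0
  K12: 501.0
  K13: 7.9
  K14: 125.0
  K15: 0.63
  K16: 985.0
  d1: 0.86
  d2: 0.017
  d3: 0.11
  d4: 0.0075
  d5: 0.001
  d6: 0.1
  delta: 0.5
  n: 3
# Biologically admissible ranges used for validation and random draws.
ranges:
  beta: [0.001, 200.0]
  K: [0.001, 2000.0]
  d: [0.001, 1.0]
  delta: [0.0, 1.0]
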