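# Reference parameterization and initial state used for the step-response
# demonstration of robust perfect adaptation.
parameters:
  k1: 3
  k2: 2
  k3: 5
  k4: 4
  k5: 5
  k6: 1
  k7: 4
  k8: 3
  k9: 1
  k10: 1.2
  k11: 1
  k12: 9
  k13: 1
  k14: 1
  k15: 1
  k16: 1
  p1: 30
  p2: 4
  p3: 1.5
  mu: 25
  eta: 10
  alpha: 10
  theta: 10
initial_state:
  Sci: 5
  C: 1
  Sr: 1
  Sh: 1
  R: 1
  Cf: 50
  Cp: 1
  Ce: 100
  E: 5
  HR: 1
  H: 1
  Sp: 1
  P: 1
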