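# Simplified winner-take-all network preset (toy paradigm, similar clusters).
experiment: toy
dataset:
  K: 7
  xi: 0.2
  kappa: 1.0e4
  n_train: 6000
  n_test: 1000
simple:
  w_rec: -1.2
  b_mature: 1.2
  b_birth: 0.9
  ramp_len: 12000
  tau_m: 20.0
  dt: 1.0
seeds:
  base: 0
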