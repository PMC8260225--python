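# Biologically plausible network preset: 100 granule cells, 25 interneurons,
# full neurogenesis paradigm on the equidistant synthetic dataset.
experiment: neurogenesis
dataset:
  K: 7
  xi: 0.2
  kappa: 1.0e4
  n_train: 6000
  n_test: 1000
network:
  n_ec: 128
  n_dgc: 100
  n_inh: 25
  p_ie: 0.9
  p_ei: 0.9
  w_ie: 1.0
  tau_m: 20.0
  tau_inh: 2.0
  L: 0.5
  p_star: 0.1
  dt: 0.1
plasticity:
  eta: 0.01
  eta_b: 0.01
  theta: 0.15
  alpha0: 0.05
  gamma0: 10.0
  beta: 1.0
  nu0: 0.2
plan:
  pretrain_classes: [0, 1]
  novel_classes: [2]
  pretrain_epochs: 80
  early_epochs: 1
  late_epochs: 1
  replacement: all
seeds:
  base: 0
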