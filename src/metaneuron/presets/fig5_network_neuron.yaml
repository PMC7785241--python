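name: fig5_network_neuron
notes: >
  eLIF neuron and 1000-cell E/I network tuned to the asynchronous-irregular
  regime (median rate ~2 Hz, ISI CV ~0.8, mean pairwise correlation below
  1/N).  The homeostasis table lists the threshold/reset compensation that
  restores the background statistics at reduced energetic health.  The
  stimulus triples the Poisson drive of the first 100 excitatory neurons for
  250 ms: at alpha >= 0.6 the subset sustains the full response, at
  alpha = 0.4 it collapses into energy block after a short onset burst.
params:
  model: elif
  Cm: 200.0
  gL: 10.0
  E0: -65.0
  Eu: -63.0
  Ef: -60.0
  Ed: -30.0
  Vth: -50.0
  Vr: -60.0
  eps0: 1.0
  epsc: 0.15
  alpha: 1.0
  tau_e: 200.0
  delta: 0.01
network:
  N: 1000
  exc_fraction: 0.8
  density: 0.1
  wE: 10.0
  wI: 50.0
  delay: 1.5
  tau_syn: 2.0
  bg_rate: 405.0
  bg_weight: 110.0
  seed: 42
  stimulus:
    subset_size: 100
    rate_multiplier: 3.0
    window: [1400.0, 1650.0]
  homeostasis:
    - {alpha: 1.0, wE_scale: 1.0, Vth_shift: 0.0, Vr_shift: 0.0}
    - {alpha: 0.8, wE_scale: 1.0, Vth_shift: 0.1, Vr_shift: 0.1}
    - {alpha: 0.6, wE_scale: 1.0, Vth_shift: 0.3, Vr_shift: 0.3}
    - {alpha: 0.4, wE_scale: 1.0, Vth_shift: 0.5, Vr_shift: 0.5}
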