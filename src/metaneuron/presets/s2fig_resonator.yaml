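name: s2fig_resonator
notes: >
  eLIF in the resonator regime (Eu < E0): energy depletion hyperpolarizes
  the cell, so voltage and energy exchange pull in opposite directions and
  the response to steps shows sag and post-inhibitory rebound.
params:
  model: elif
  Cm: 200.0
  gL: 10.0
  E0: -65.0
  Eu: -70.0
  Ef: -60.0
  Ed: -45.0
  Vth: -50.0
  Vr: -58.0
  eps0: 1.0
  epsc: 0.1
  alpha: 1.0
  tau_e: 300.0
  delta: 0.02
protocol:
  duration: 2500.0
  segments:
    - [500.0, 1500.0, -100.0]
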