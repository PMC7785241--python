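name: fig3_bistable
notes: >
  eLIF tuned into the bistable regime at zero current: three fixed points
  (rested/stable, saddle, depleted/stable).  Brief current pulses switch
  between the two stable states; a long strong step drives spiking into
  depolarization block and back.
params:
  model: elif
  Cm: 200.0
  gL: 10.0
  E0: -65.0
  Eu: -59.0
  Ef: -64.0
  Ed: -48.0
  Vth: -58.0
  Vr: -68.0
  eps0: 1.0
  epsc: 0.15
  alpha: 1.0
  tau_e: 300.0
  delta: 0.05
protocol:
  duration: 3000.0
  segments:
    - [100.0, 1100.0, 80.0]
protocols:
  block:
    duration: 3000.0
    segments:
      - [100.0, 1100.0, 80.0]
  switch:
    duration: 9000.0
    segments:
      - [1500.0, 3000.0, 50.0]
      - [6000.0, 6500.0, -80.0]
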