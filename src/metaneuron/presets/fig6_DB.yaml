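name: fig6_DB
notes: 'Delayed bursting: an amplifying subthreshold adaptation current (a < 0)
  slowly depolarizes the cell during the step, so firing starts late and arrives
  in bursts shaped by the above-threshold reset. Red-protocol currents produce depolarization
  block.'
params: {model: madexp, Cm: 100.0, gL: 10.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.15, tau_e: 500.0, delta: 0.02, Ef: -55.0, Ed: -35.0, gamma: 10000.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -65.0, Vth: -50.0, Vr: -47.0, a: -10.0, tau_w: 90.0,
  b: 30.0, Eu: -65.0}
protocol: &id001
  duration: 1500.0
  segments:
  - [100.0, 1100.0, 30.0]
protocols:
  yellow: *id001
  red:
    duration: 1500.0
    segments:
    - [100.0, 1100.0, 700.0]
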