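name: fig6_DA
notes: 'Delayed accelerating: a slow amplifying adaptation current (a < 0, long
  tau_w) makes firing start late in the step and speed up steadily. Red-protocol
  currents produce depolarization block.'
params: {model: madexp, Cm: 200.0, gL: 12.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.15, tau_e: 500.0, delta: 0.02, Ef: -55.0, Ed: -35.0, gamma: 10000.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -70.0, Vth: -50.0, Vr: -58.0, a: -10.0, tau_w: 300.0,
  b: 0.0, Eu: -70.0}
protocol: &id001
  duration: 1500.0
  segments:
  - [100.0, 1100.0, 125.0]
protocols:
  yellow: *id001
  red:
    duration: 1500.0
    segments:
    - [100.0, 1100.0, 600.0]
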