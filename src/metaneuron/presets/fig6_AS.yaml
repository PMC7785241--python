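name: fig6_AS
notes: 'Adaptive spiker: slow spike-triggered adaptation (large b, long tau_w) progressively
  lengthens the ISIs during the step. High currents (red) drive the energy below
  the critical level into depolarization block.'
params: {model: madexp, Cm: 200.0, gL: 10.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.16, tau_e: 100.0, delta: 0.1, Ef: -48.0, Ed: -36.0, gamma: 2000.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -70.0, Vth: -50.0, Vr: -58.0, a: 2.0, tau_w: 300.0,
  b: 60.0, Eu: -70.0}
protocol: &id001
  duration: 1500.0
  segments:
  - [100.0, 1100.0, 350.0]
protocols:
  yellow: *id001
  red:
    duration: 1500.0
    segments:
    - [100.0, 1100.0, 1200.0]
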