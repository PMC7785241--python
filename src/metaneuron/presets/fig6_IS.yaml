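name: fig6_IS
notes: 'Intermittent spiking: the mean drive sits just below ignition and a weak
  Poisson background triggers spiking epochs at irregular, noise-dominated intervals;
  each epoch drains the energy variable, which must recover before the next one.
  Uses a long step so several epochs are observed. Red-protocol currents produce
  sustained depolarization block.'
params: {model: madexp, Cm: 200.0, gL: 10.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.1, tau_e: 100.0, delta: 0.12, Ef: -50.0, Ed: -35.0, gamma: 10000.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -65.0, Vth: -50.0, Vr: -49.5, a: 0.0, tau_w: 30.0,
  b: 0.0, Eu: -65.0}
protocol: &id001
  duration: 8200.0
  segments:
  - [100.0, 8100.0, 88.0]
  poisson: &id002 {rate: 100.0, weight: 120.0, kind: exp, tau_syn: 2.0}
protocols:
  yellow: *id001
  red:
    duration: 8200.0
    segments:
    - [100.0, 8100.0, 500.0]
    poisson: *id002
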