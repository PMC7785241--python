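name: fig6_ER
notes: 'Post-excitatory rebound: with Eu far below E0 and a fast energy variable,
  depletion during a depolarizing step hyperpolarizes the leak and accommodates
  the response, so the step itself stays subthreshold. At the offset the recovering
  energy and adaptation ring back through an overshoot that ignites spikes only
  after the step ends. Very large currents (red protocol) outrun the fast energy
  production and produce depolarization block.'
params: {model: madexp, Cm: 200.0, gL: 10.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.1, tau_e: 8.0, delta: 0.15, Ef: -51.0, Ed: -31.0, gamma: 10000.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -52.0, Eu: -82.0, Vth: -50.0, Vr: -58.0, a: 10.0,
  tau_w: 30.0, b: 0.0}
protocol: &id001
  duration: 1500.0
  segments:
  - [100.0, 1100.0, 90.0]
protocols:
  yellow: *id001
  red:
    duration: 1500.0
    segments:
    - [100.0, 1100.0, 2500.0]
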