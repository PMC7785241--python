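name: fig6_IB
notes: 'Initial burst: the reset above threshold produces a fast opening volley
  until adaptation accumulates, after which spiking settles to a slower regular
  rhythm. Red-protocol currents push the cell into depolarization block.'
params: {model: madexp, Cm: 130.0, gL: 18.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.15, tau_e: 500.0, delta: 0.02, Ef: -55.0, Ed: -35.0, gamma: 10000.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -58.0, Vth: -50.0, Vr: -48.0, a: 4.0, tau_w: 150.0,
  b: 120.0, Eu: -58.0}
protocol: &id001
  duration: 1500.0
  segments:
  - [100.0, 1100.0, 350.0]
protocols:
  yellow: *id001
  red:
    duration: 1500.0
    segments:
    - [100.0, 1100.0, 1000.0]
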