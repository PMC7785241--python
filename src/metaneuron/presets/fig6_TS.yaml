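name: fig6_TS
notes: 'Transient spiking: a fast, small energy pool with a high critical level
  supports only an initial volley; the energy variable then sags below the spiking
  level and recovers only after the step ends. Red-protocol currents hold the cell
  in depolarization block.'
params: {model: madexp, Cm: 100.0, gL: 10.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.2, tau_e: 60.0, delta: 0.05, Ef: -65.0, Ed: -35.0, gamma: 500.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -65.0, Vth: -50.0, Vr: -58.0, a: 10.0, tau_w: 150.0,
  b: 30.0, Eu: -65.0}
protocol: &id001
  duration: 1500.0
  segments:
  - [100.0, 1100.0, 250.0]
protocols:
  yellow: *id001
  red:
    duration: 1500.0
    segments:
    - [100.0, 1100.0, 500.0]
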