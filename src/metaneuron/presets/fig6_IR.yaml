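name: fig6_IR
notes: 'Post-inhibitory rebound: strong subthreshold adaptation (a >> gL) makes
  the cell a resonator; releasing a hyperpolarizing step (blue protocol, negative
  current) leaves a negative adaptation current that overshoots the rest potential
  and fires rebound spikes. Red-protocol currents produce depolarization block.'
params: {model: madexp, Cm: 200.0, gL: 10.0, Ie_baseline: 0.0, eps0: 1.0, alpha: 1.0,
  epsc: 0.15, tau_e: 500.0, delta: 0.02, Ef: -55.0, Ed: -35.0, gamma: 10000.0, I_KATP: 0.0,
  Vpeak: 0.0, DeltaT: 2.0, E0: -65.0, Vth: -50.0, Vr: -58.0, a: 40.0, tau_w: 200.0,
  b: 0.0, Eu: -65.0}
protocol: &id001
  duration: 1500.0
  segments:
  - [100.0, 1100.0, -300.0]
protocols:
  blue: *id001
  red:
    duration: 1500.0
    segments:
    - [100.0, 1100.0, 1600.0]
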