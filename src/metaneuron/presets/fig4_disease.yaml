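name: fig4_disease
notes: >
  eLIF configured so that sweeping the energetic-health parameter alpha from
  1.0 down to 0.3 passes through four qualitative stages (healthy rest,
  bistable, spontaneously spiking, energy-blocked).  The named protocols
  play the decline out in time at two speeds; both end in the depolarized
  energy-blocked state, with a transient spontaneous-spiking window whose
  length scales with the decline duration.
params:
  model: elif
  Cm: 200.0
  gL: 10.0
  E0: -70.0
  Eu: -60.0
  Ef: -66.0
  Ed: -46.0
  Vth: -63.0
  Vr: -70.0
  eps0: 1.0
  epsc: 0.16
  alpha: 1.0
  tau_e: 300.0
  delta: 0.05
protocol:
  duration: 2000.0
protocols:
  decline_fast:
    duration: 40000.0
    alpha_schedule:
      - [0.0, 1.0]
      - [35000.0, 0.3]
  decline_slow:
    duration: 50000.0
    alpha_schedule:
      - [0.0, 1.0]
      - [45000.0, 0.3]
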