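"""Single-neuron simulation: a regular-spiking mAdExp cell.

Runs the shipped fig6_RS preset through its standard step protocol,
prints spike times, and shows how the energy reserve dips with each
spike and recovers after the step ends.

Usage: python examples/01_single_neuron.py
"""

import numpy as np

from metaneuron import integrate, preset_params, preset_protocol

params = preset_params("fig6_RS")
proto = preset_protocol("fig6_RS")          # 1 s current step inside 1.5 s

res = integrate(params, None, proto, dt=0.05, seed=0)

print(f"simulated {proto.duration:.0f} ms at dt = 0.05 ms")
print(f"{res.n_spikes} spikes; first three at "
      + ", ".join(f"{t:.2f} ms" for t in res.spike_times[:3]))

# energy cost of spiking: eps drops by `delta` per spike and recovers
# toward alpha * eps0 between spikes
step_mask = (res.t >= 100.0) & (res.t <= 1100.0)
print(f"energy during the step: min {res.eps[step_mask].min():.3f}, "
      f"gate epsc = {params.epsc}")
print(f"energy at end of run (post-step recovery): {res.eps[-1]:.3f}")

# the same cell driven hard enough enters depolarization block: the
# reserve falls below epsc and the spike-initiation current shuts off
strong = preset_protocol("fig6_RS", "red")
res_block = integrate(params, None, strong, dt=0.05, seed=0)
print(f"\nstrong drive: {res_block.n_spikes} spikes, then "
      f"silence with V stuck near {res_block.V[-1]:.1f} mV "
      f"and eps = {res_block.eps.min():.3f} < epsc")
print(f"alive at end: {res_block.death_time is None}")
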