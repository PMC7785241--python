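"""Sparse E/I network in the asynchronous-irregular regime.

Builds a reduced (200-neuron) version of the shipped network preset,
simulates 3 s of background activity, and reports the statistics that
define the asynchronous-irregular state: low rates, irregular spiking
(ISI CV near 1) and pairwise correlations below 1/N.

The full acceptance-scale run (1000 neurons, 5.5 s) is what
scripts/acceptance.py computes; this example keeps N small so it
finishes in a few seconds.

Usage: python examples/04_network.py
"""

import dataclasses

from metaneuron import (
    build_network,
    compute_stats,
    is_asynchronous_irregular,
    preset_network,
    preset_params,
    simulate_network,
)

spec = preset_network("fig5_network_neuron")
spec = dataclasses.replace(spec, N=200, stimulus=None, seed=1)
params = preset_params("fig5_network_neuron")

net = build_network(spec)
n_exc = int(net.is_exc.sum())
print(f"network: N = {spec.N} ({n_exc} excitatory), "
      f"{net.n_edges} synapses (density {spec.density})")

warmup, duration = 500.0, 3500.0
res = simulate_network(net, params, duration, dt=0.1, seed=1)
stats = compute_stats(res.spike_trains, (warmup, duration), seed=1)

print(f"median rate : {stats.median_rate:.2f} Hz")
print(f"mean ISI CV : {stats.mean_cv:.2f}")
print(f"mean pair CC: {stats.mean_cc:.4f}  (1/N = {1.0 / spec.N:.4f})")
print("asynchronous-irregular:",
      is_asynchronous_irregular(stats, spec.N))

# homeostatic compensation lets the network keep firing as health drops
res_sick = simulate_network(net, params, duration, dt=0.1, seed=1,
                            alpha=0.6)
stats_sick = compute_stats(res_sick.spike_trains, (warmup, duration),
                           seed=1)
print(f"\nat alpha = 0.6 (with homeostasis): "
      f"median rate {stats_sick.median_rate:.2f} Hz, "
      f"mean CC {stats_sick.mean_cc:.4f}")
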