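"""Phase-plane structure and the health-decline (alpha) sweep.

Locates the fixed points of the bistable preset, prints the saddle-node
current interval that bounds the bistable region, then sweeps the
energetic-health parameter alpha of the disease-progression preset from
1.0 down to 0.3 and prints the resulting stage sequence.

Usage: python examples/02_phase_plane_and_health.py
"""

from metaneuron import (
    alpha_sweep,
    classify_regime,
    find_fixed_points,
    preset_params,
    saddle_node_currents,
)

# ---------------------------------------------------------- bistability
p = preset_params("fig3_bistable")

print("fixed points of the bistable preset at I = 0:")
for fp in find_fixed_points(p, 0.0):
    print(f"  V = {fp.V:8.3f} mV, eps = {fp.eps:.4f}  ({fp.stability})")
print(f"regime: {classify_regime(p, 0.0)!r}")

sn = saddle_node_currents(p)
print(f"three fixed points coexist for I in "
      f"({sn.I_minus:.2f}, {sn.I_plus:.2f}) pA")

# outside that interval a saddle-node bifurcation has removed the pair
for I in (sn.I_minus - 5.0, sn.I_plus + 5.0):
    n = len(find_fixed_points(p, I))
    print(f"  at I = {I:6.2f} pA: {n} fixed point(s)")

# ------------------------------------------------------- health decline
pd = preset_params("fig4_disease")
grid = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3]
rows, stages = alpha_sweep(pd, grid)

print("\ndisease progression (declining alpha):")
for alpha, fps, regime in rows:
    print(f"  alpha = {alpha:.1f}: {len(fps)} fixed point(s), {regime}")
print("stage sequence:", " -> ".join(stages))
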