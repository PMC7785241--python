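"""Behavior classification across the shipped preset library.

Simulates each behavior preset through its standard step protocol and
runs the rule-based classifier, printing the label and a few of the
features it was decided on.  Every preset should classify as its own
label, and every preset driven with its strong ("red") current should
enter depolarization block.

Usage: python examples/03_behavior_classifier.py
"""

from metaneuron import (
    classify_response,
    integrate,
    preset_params,
    preset_protocol,
)

PRESETS = {
    "fig6_RS": "yellow", "fig6_AS": "yellow", "fig6_IB": "yellow",
    "fig6_RB": "yellow", "fig6_TS": "yellow", "fig6_DB": "yellow",
    "fig6_DA": "yellow", "fig6_IR": "blue", "fig6_ER": "yellow",
    "fig6_IS": "yellow",
}

print(f"{'preset':10s} {'label':12s} {'spikes':>6s} {'adapt':>7s} "
      f"{'bursts':>6s} {'rebound':>7s}")
for name, key in PRESETS.items():
    params = preset_params(name)
    proto = preset_protocol(name, key)
    res = integrate(params, None, proto, dt=0.05, seed=0)
    report = classify_response(res, proto)
    f = report.features
    adapt = f"{f.adaptation_index:7.2f}" if f.adaptation_index is not None else "      -"
    bursts = f"{f.n_bursts:6d}" if f.n_bursts is not None else "     -"
    print(f"{name:10s} {report.label:12s} {f.n_spikes_step:6d} "
          f"{adapt} {bursts} {f.rebound_count:7d}")

print("\nstrong drive -> depolarization block:")
for name in ("fig6_RS", "fig6_IB"):
    params = preset_params(name)
    proto = preset_protocol(name, "red")
    res = integrate(params, None, proto, dt=0.05, seed=0)
    print(f"  {name}: {classify_response(res, proto).label}")
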