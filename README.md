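# metaneuron

Energy-constrained hybrid neuron models — simulation, phase-plane analysis,
spiking-behavior classification, asynchronous-irregular network studies, and
subthreshold fitting.

## The models

Standard integrate-and-fire models assume an unlimited energy supply: a
neuron can fire whenever its membrane potential reaches threshold.
`metaneuron` implements two hybrid models in which spiking is conditional on
a metabolic energy reserve:

* **eLIF** — a leaky integrate-and-fire neuron augmented with an energy
  variable `eps` (a phenomenological ATP/ADP proxy).  Energy is produced
  toward a sustainable level `alpha * eps0` (with `alpha` in (0, 1] the
  neuron's *energetic health*) and consumed by depolarization; each spike
  costs a fixed amount `delta`.  The leak reversal shifts with energy
  (between `E0` at full reserve and `Eu` when depleted), and a spike is
  emitted only when the voltage crosses threshold **and** `eps >= epsc`.
* **mAdExp** — an adaptive exponential integrate-and-fire neuron whose
  spike-initiation exponential is scaled by `(eps - epsc) / eps0`, whose
  adaptation current includes an ATP-gated potassium (K-ATP) term, and whose
  energy consumption grows with the adaptation current.

These ingredients produce regimes classical models do not have:
depolarization block when the reserve falls below `epsc`, energy-mediated
bistability between a high-energy rest and a depolarized low-energy state,
rebound firing without sag, a four-stage progression of dynamical regimes as
health `alpha` declines, and neuronal death as an absorbing state.

## Quick start (Python)

```python
from metaneuron import integrate, preset_params, preset_protocol

params = preset_params("fig6_RS")          # a regular-spiking mAdExp cell
proto = preset_protocol("fig6_RS")         # 1 s step of 230 pA
res = integrate(params, None, proto, dt=0.05, seed=0)
print(res.n_spikes, res.spike_times[:3])   # 15 spikes, ~ms precision
```

Phase-plane structure of a bistable cell:

```python
from metaneuron import find_fixed_points, classify_regime, preset_params

p = preset_params("fig3_bistable")
for fp in find_fixed_points(p, 0.0):
    print(f"V = {fp.V:.2f} mV, eps = {fp.eps:.3f} ({fp.stability})")
print(classify_regime(p, 0.0))             # "bistable"
```

See `examples/` for commented walkthroughs of the single-neuron dynamics,
the phase-plane and health-decline analysis, the behavior classifier, and
the network simulator.

## Quick start (command line)

```
$ metaneuron presets                       # list shipped parameter sets
$ metaneuron phase --preset fig3_bistable --out out_phase
I = 0 pA: 3 fixed point(s), regime 'bistable'
  V = -62.000 mV, eps = 0.5000 (stable)
  V = -63.902 mV, eps = 0.8170 (saddle)
  V = -69.098 mV, eps = 1.6830 (stable)
wrote out_phase/nullclines.tsv and out_phase/fixed_points.tsv

$ metaneuron simulate --preset fig6_RS --out out_sim
simulated 1500 ms: 15 spikes, alive; wrote out_sim/trace.tsv and out_sim/spikes.txt

$ metaneuron classify --preset fig6_RS --out out_cls
RS
wrote out_cls/features.tsv
```

Subcommands: `simulate`, `phase`, `sweep-alpha`, `network`, `classify`,
`fit`, `make-fixtures`, `presets`.  Every subcommand takes `--config FILE`
(a YAML configuration) or `--preset NAME`, plus `--out DIR`, `--seed N` and
`--dt MS`.  Exit code is 0 on success; validation errors exit nonzero with a
one-line `error: ...` diagnostic.  All output files are plain text with
`#`-prefixed metadata headers that record the seed, time step and source
configuration, e.g.:

```
# command = simulate
# source = preset:fig6_RS
# seed = 0
# dt_ms = 0.05
# n_spikes = 15
# columns = t_ms V_mV eps w_pA
0       -70     1       0
...
```

## Package layout

| Module | Contents |
| --- | --- |
| `metaneuron.models` | Parameter dataclasses, right-hand sides, spike/reset rules |
| `metaneuron.simulate` | Hybrid integrator (RK4/Euler, within-step spike localization, refractoriness, Poisson input, death) |
| `metaneuron.phase` | Nullclines, fixed points and stability, saddle-node currents, regime classification, health sweeps |
| `metaneuron.behavior` | Feature extraction and the rule-based spiking-behavior classifier |
| `metaneuron.network` | Sparse E/I networks with Poisson drive, homeostasis table, spike-train statistics |
| `metaneuron.fitting` | Subthreshold estimators (resting potential, membrane time constant, total conductance), sweep files, trace discrepancy |
| `metaneuron.config` / `metaneuron.presets` | YAML configurations and the shipped preset library |
| `metaneuron.cli` | The `metaneuron` command-line entry point |
| `metaneuron.fixtures` | Deterministic generator of all test fixtures |

`docs/methods.md` documents the equations, numerical methods and classifier
rules in full.

## Tests and acceptance targets

```
python -m pytest            # full suite
python scripts/acceptance.py --seed 0 --out acceptance.json
```

`scripts/acceptance.py` recomputes the quantitative targets from scratch —
the median rate and ISI irregularity of the 1000-neuron
asynchronous-irregular network preset, the fixed-point structure of the
bistable preset, and the four-stage health-decline progression — and writes
them as JSON.  `tests/test_acceptance.py` restates each acceptance
criterion as one test.
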