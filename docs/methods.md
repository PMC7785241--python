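# Methods

Units throughout: membrane potential in mV, time in ms, currents in pA,
conductances in nS, capacitance in pF.  The energy variable `eps` and the
health factor `alpha` are dimensionless.

## 1. Models

### 1.1 eLIF (energy-dependent leaky integrate-and-fire)

State: membrane potential `V`, available energy `eps`.

```
Cm dV/dt   = gL (EL(eps) - V) + I(t)
tau_e deps/dt = (1 - eps / (alpha eps0))^3 - (V - Ef) / (Ed - Ef)
EL(eps)    = E0 + (Eu - E0)(1 - eps / eps0)
```

The first term of the energy equation is production, relaxing `eps` toward
the sustainable level `alpha * eps0` (the cubic makes production saturate
near the sustainable level and grow sharply under depletion).  The second
term is consumption, zero at the *flex potential* `Ef` and equal to 1 at the
*depolarization potential* `Ed`.  The leak reversal `EL` slides between `E0`
(full reserve, `eps = eps0`) and `Eu` (empty reserve, `eps = 0`).

Spike rule: when `V >= Vth` **and** `eps >= epsc`, a spike is recorded and
the state resets to `V <- Vr`, `eps <- eps - delta`.  With `Eu = E0` and
`delta = 0` the model reduces exactly to the standard LIF.

### 1.2 mAdExp (modified adaptive exponential integrate-and-fire)

State: `V`, `eps`, adaptation current `w`.

```
Cm dV/dt   = gL (EL(eps) - V)
             + gL DeltaT ((eps - epsc)/eps0) exp((Vx - Vth)/DeltaT)
             - w + I(t)
tau_e deps/dt = (1 - eps/(alpha eps0))^3 - (Vx - Ef)/(Ed - Ef) - w/gamma
tau_w dw/dt   = a (Vx - EL(eps)) - w + katp
katp          = (epsc / (epsc + 2 eps)) I_KATP
```

`Vx = min(V, Vpeak)` caps the exponential, energy and adaptation equations
during the spike upswing; the exponent is additionally clamped at 20.  The
exponential spike-initiation term is scaled by the available energy margin
`(eps - epsc)/eps0`: it vanishes at `eps = epsc` (no regenerative upswing
without energy — depolarization block) and is negative below it.  `katp` is
an ATP-gated potassium current that activates as the reserve empties.
Energy consumption gains a `w/gamma` term: adaptation costs energy.

Spike rule: when `V >= Vpeak`, reset `V <- Vr`, `eps <- eps - delta`,
`w <- w + b`.  With `eps` pinned at `eps0 + epsc`, `Eu = E0` and
`gamma -> inf`, the model reduces exactly to the textbook AdExp.

### 1.3 Death

If `eps <= 0` while `V >= Ed` (consumption exceeding any possible
production at a fully depleted reserve), the neuron is declared dead: the
state freezes at its current value and no further dynamics or spikes occur.
This is an absorbing state; `SimulationResult.death_time` records the time.

## 2. Numerical integration

`integrate()` advances the continuous dynamics with classical RK4 (or
explicit Euler) at a fixed step `dt`, then applies the discrete rules.
Spikes are localized *within* the step: the threshold crossing time is
estimated by linear interpolation between the pre- and post-step states, the
reset is applied at the crossing, and the remainder of the step is
integrated from the reset state.  For the eLIF the crossing time is the
later of the voltage-threshold and energy-gate crossings (both conditions
must hold).  For the mAdExp, steps along the exponential upswing (`V >=
Vpeak` or a step change above 1 mV) are redone with 16 substeps with
per-substep crossing detection, because the upswing is too fast for the
outer step.  With this scheme, halving `dt` moves every spike time by at
most `2 dt` for all shipped presets.

Refractoriness clamps `V = Vr` for the configured period after a spike.
Poisson input is generated per step from the seeded generator, delivered
either as an exponentially decaying current (`tau_syn`, default) or as
instantaneous charge (`delta` kind).  A `Protocol` combines step-current
segments (overlaps sum), optional Poisson input, and an optional
piecewise-linear `alpha(t)` schedule.

## 3. Phase-plane analysis (eLIF; mAdExp via root finding)

With the voltage nullcline `V = EL(eps) + I/gL` substituted into the energy
equation, fixed points are roots of a cubic in `eps`.  `find_fixed_points`
locates them by a dense sign scan plus Brent refinement (eLIF) or by
multi-seeded Newton iteration on the full 3-D system (mAdExp); stability
comes from the Jacobian eigenvalues.  `classify_regime` maps the fixed-point
structure onto `single-rest`, `bistable` (two stable states separated by a
saddle), `tonic-spiking`, `energy-blocked` or `nonviable`.

`saddle_node_currents` returns the interval `(I-, I+)` over which three
fixed points coexist; in closed form

```
I+- = gL [ Ef - Eu + alpha (Eu - E0) (1 +- (2/3) sqrt(alpha (Eu - E0) / (3 (Ed - Ef)))) ]
```

degenerating to the single value `gL (Ef - E0)` at `Eu = E0`.
`rebound_threshold` gives the effective threshold shift at an empty reserve,
`V* = Vth + DeltaT ln((Eu - E0)/DeltaT)`, the mechanism behind rebound
spiking without sag; it applies when `0 < Eu - E0 < DeltaT`.
`alpha_sweep` evaluates the regime along a declining-health grid and
compresses it into the stage sequence (the shipped disease preset passes
through `single-rest -> bistable -> tonic-spiking -> energy-blocked`).

## 4. Behavior classification

`extract_features` reduces the response to a single-step protocol to a
feature set: spike counts in and after the step, latency, the ISI sequence
and its adaptation index `(last - first)/(last + first)`, burstiness (ratio
of the short- to long-class median after a 2-means split of log ISIs),
burst count and inter-burst gap regularity, monotone-lengthening fraction,
sag ratio (hyperpolarizing steps), rebound spikes within 300 ms of the
offset, early stopping, depolarization-block intervals (superthreshold
silence with `eps < epsc`, minimum 50 ms), and end-of-step energy recovery.

`classify` applies deterministic threshold rules in priority order:
depolarization block; post-inhibitory / post-excitatory rebound (IR/ER);
delayed bursting / delayed accelerating (DB/DA); initial-burst, regular
bursting and intermittent spiking (IB/RB/IS); transient spiking (TS);
adapting (AS); regular spiking (RS); silent.  All thresholds live in
`ClassifierThresholds` and are plain package defaults.  A smoothly
lengthening ISI sequence is kept in the adapting family even when mildly
bimodal.  `rebound_mode` separates the two rebound mechanisms: sag-mediated
(adaptation current) versus no-sag (energy-mediated).

## 5. Networks

`build_network` realizes a directed Erdos-Renyi graph (density `p`, no
self-loops, reproducible from the spec seed) over `N` neurons, 80%
excitatory by default.  All neurons share one parameter set.  Synapses are
current-based exponentials with transmission delay (ring buffer); each
neuron receives an independent Poisson background drive.  The homeostasis
table maps a health level `alpha` to compensations (excitatory-weight scale,
threshold/reset shifts); `entry_for` picks the nearest tabulated `alpha`.
An optional stimulus multiplies the background rate of a target subset
within a time window.  The network integrator is vectorized RK4 with
end-of-step spike detection at `dt = 0.1` ms.

`compute_stats` reports per-neuron rates, ISI CVs (neurons with >= 5 spikes)
and the mean pairwise Pearson correlation of spike counts in 5 ms bins over
a seeded random sample of pairs.  The asynchronous-irregular criterion is
`mean CC < 1/N` with mean CV in [0.5, 1.2].

## 6. Subthreshold fitting

From a set of current-clamp sweeps (`Sweep`: uniform sampling, one step per
sweep):

* `estimate_EL` — median voltage pooled over all baseline windows.
* `estimate_gL_plus_a` — reciprocal slope of the steady-state deflection
  versus current (least squares over all nonzero subthreshold sweeps).
* `estimate_tau_m` — effective membrane time constant from a joint fit of
  the shared RC model `V = v0 + c_s + (I_s/g)(1 - exp(-t/tau))` to all
  subthreshold sweeps (free offset per sweep, one shared conductance, one
  shared `tau`; linear parameters profiled out, `tau` by log-grid scan with
  golden-section refinement).  For a pure RC response this returns `Cm/gL`
  exactly; for a cell with fast subthreshold adaptation it returns
  `Cm/(gL + a)`, consistent with the conductance estimator.  Each sweep's
  onset is sanity-checked by a linear fit over the first `max(5 ms, 5%)` of
  the step; noise-dominated sweeps are skipped with a warning.

`discrepancy` scores a simulation against a target trace: subthreshold RMSE
(spikes masked +-5 ms) + 10 per spike-count difference + 0.1 per ms of mean
matched spike-time difference.

## 7. Reproducibility

Every stochastic element (Poisson inputs, network graphs, pair subsampling,
fixture noise) flows from an explicit integer seed, and every output file
records its seed, time step and source configuration in `#`-prefixed
headers.  `metaneuron make-fixtures` regenerates all test fixtures
deterministically from one seed.
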