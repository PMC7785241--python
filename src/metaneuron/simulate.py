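"""Single-neuron time-stepping with spike/reset rules, death and recording.

The smooth flow is integrated with a fixed-step classical Runge-Kutta scheme
(RK4 by default, explicit Euler available) and the hybrid rules are applied at
the end of each step:

* eLIF fires when ``V >= Vth`` and ``eps >= epsc`` — a superthreshold neuron
  with depleted energy keeps evolving continuously instead (depolarization
  block);
* mAdExp fires at the numerical cutoff ``V >= Vpeak``;
* the reset jumps ``V -> Vr``, ``eps -> eps - delta`` (and ``w -> w + b``);
* death is declared when ``eps <= 0`` while ``V >= Ed``, after which the
  state freezes.

When a step ends above the firing level the crossing is located within the
step by linear interpolation, the reset is applied at the crossing, and the
remainder of the step is integrated from the reset state.  This keeps spike
times second-order accurate and prevents the per-spike timing drift of plain
end-of-step detection.  Applied currents are piecewise constant (protocol
segments snap to the step grid).  Poisson input is delivered as current,
either as an exponentially decaying synaptic current (default) or as
instantaneous charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import IntegrationError
from .models import ELIFParams, MAdExpParams, NeuronState, Params, effective_leak

#: substep refinement of steep (spike-upswing) steps: a step whose voltage
#: grows by more than _STEEP_DV mV is redone with _N_SUB substeps
_STEEP_DV = 1.0
_N_SUB = 16

__all__ = [
    "PoissonInput",
    "Protocol",
    "SimulationResult",
    "integrate",
    "detect_depolarization_block",
]


@dataclass(frozen=True)
class PoissonInput:
    """Poisson background input delivered as current.

    ``kind="exp"``: each event adds ``weight`` pA to an exponentially decaying
    synaptic current with timescale ``tau_syn``.  ``kind="delta"``: each event
    deposits the charge ``weight`` (pA*ms), i.e. an instantaneous voltage jump
    of ``weight / Cm``.
    """

    rate: float  # Hz
    weight: float  # pA (exp) or pA*ms of charge (delta)
    kind: str = "exp"
    tau_syn: float = 2.0  # ms

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("Poisson rate must be non-negative")
        if self.kind not in ("exp", "delta"):
            raise ValueError("Poisson input kind must be 'exp' or 'delta'")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")


@dataclass(frozen=True)
class Protocol:
    """A stimulation protocol: step currents, optional noise, optional
    time-varying energetic health.

    ``segments`` is a list of ``(start_ms, stop_ms, amplitude_pA)`` tuples
    (overlapping segments sum).  ``alpha_schedule`` is a piecewise-linear
    ``alpha(t)`` given as ``(t_ms, alpha)`` knots, evaluated once per step.
    """

    duration: float
    segments: Sequence[tuple[float, float, float]] = ()
    poisson: Optional[PoissonInput] = None
    alpha_schedule: Optional[Sequence[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        # normalize container types so value-equal protocols compare equal
        object.__setattr__(
            self, "segments", tuple(tuple(s) for s in self.segments)
        )
        if self.alpha_schedule is not None:
            object.__setattr__(
                self,
                "alpha_schedule",
                tuple(tuple(k) for k in self.alpha_schedule),
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for start, stop, _ in self.segments:
            if not (0.0 <= start <= stop <= self.duration):
                raise ValueError(
                    f"segment ({start}, {stop}) outside [0, {self.duration}]"
                )

    def current_array(self, dt: float, n_steps: int) -> np.ndarray:
        """Applied current per step, evaluated at step-start times."""
        t = np.arange(n_steps) * dt
        I = np.zeros(n_steps)
        for start, stop, amp in self.segments:
            I[(t >= start) & (t < stop)] += amp
        return I

    def alpha_array(
        self, dt: float, n_steps: int, alpha_default: float
    ) -> Optional[np.ndarray]:
        if self.alpha_schedule is None:
            return None
        knots = sorted(self.alpha_schedule)
        tk = np.array([k[0] for k in knots])
        ak = np.array([k[1] for k in knots])
        if np.any(ak <= 0) or np.any(ak > 1):
            raise ValueError("scheduled alpha values must lie in (0, 1]")
        t = np.arange(n_steps) * dt
        return np.interp(t, tk, ak, left=ak[0], right=ak[-1])


@dataclass
class SimulationResult:
    """Sampled traces, spike times and viability flags of one simulation."""

    t: np.ndarray  # ms
    V: np.ndarray  # mV
    eps: np.ndarray
    w: np.ndarray  # pA
    spike_times: np.ndarray  # ms, strictly increasing
    death_time: Optional[float]  # ms, or None if the neuron survived
    dt: float
    params: Params

    @property
    def alive(self) -> bool:
        return self.death_time is None

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


def default_state(p: Params) -> NeuronState:
    """Rest-like initial state: leak potential at the sustainable energy."""
    e0 = p.alpha * p.eps0
    return NeuronState(V=effective_leak(e0, p), eps=e0, w=0.0)


def integrate(
    p: Params,
    s0: Optional[NeuronState],
    proto: Protocol,
    dt: float = 0.05,
    seed: int = 0,
    method: str = "rk4",
    refractory: float = 0.0,
    record_every: int = 1,
) -> SimulationResult:
    """Integrate one neuron through a protocol.

    Deterministic given ``(p, s0, proto, dt, seed)``.  ``record_every``
    subsamples the stored traces (spike detection still happens every step).
    ``refractory`` clamps the voltage at ``Vr`` for the given time after each
    spike (default 0 ms: no refractoriness).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("rk4", "euler"):
        raise ValueError("method must be 'rk4' or 'euler'")
    if s0 is None:
        s0 = default_state(p)
    if not s0.alive:
        raise ValueError("initial state is not alive")

    madexp = isinstance(p, MAdExpParams)
    n_steps = int(round(proto.duration / dt))
    I_arr = proto.current_array(dt, n_steps) + p.Ie_baseline
    alpha_arr = proto.alpha_array(dt, n_steps, p.alpha)

    rng = np.random.default_rng(seed)
    poisson = proto.poisson
    if poisson is not None and poisson.rate > 0:
        lam = poisson.rate * dt * 1e-3
        n_events = rng.poisson(lam, n_steps)
    else:
        n_events = None

    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    V_out = np.empty(n_rec)
    e_out = np.empty(n_rec)
    w_out = np.empty(n_rec)

    # locals for speed in the inner loop
    Cm, gL, E0, Eu, Ef, Ed = p.Cm, p.gL, p.E0, p.Eu, p.Ef, p.Ed
    Vth, Vr, eps0, epsc = p.Vth, p.Vr, p.eps0, p.epsc
    tau_e, delta = p.tau_e, p.delta
    dEdF = Ed - Ef
    if madexp:
        DeltaT, Vpeak, a, b = p.DeltaT, p.Vpeak, p.a, p.b
        tau_w, gamma, IKATP = p.tau_w, p.gamma, p.I_KATP
    alpha = p.alpha
    exp = math.exp

    if poisson is not None:
        syn_decay = exp(-dt / poisson.tau_syn)
        is_delta = poisson.kind == "delta"
        pw = poisson.weight

    V, e, w = s0.V, s0.eps, s0.w
    I_syn = 0.0
    spikes: list[float] = []
    death_time: Optional[float] = None
    refrac_until = -1.0

    t_out[0], V_out[0], e_out[0], w_out[0] = 0.0, V, e, w
    rec_i = 1
    h = dt

    def deriv_elif(V, e, Itot, alpha):
        dV = (gL * (E0 + (Eu - E0) * (1.0 - e / eps0) - V) + Itot) / Cm
        de = ((1.0 - e / (alpha * eps0)) ** 3 - (V - Ef) / dEdF) / tau_e
        return dV, de

    def deriv_madexp(V, e, w, Itot, alpha):
        EL = E0 + (Eu - E0) * (1.0 - e / eps0)
        # cap the voltage seen by the exponential and the coupled equations
        # at the cutoff: beyond it the upswing is unphysical and about to be
        # reset, and must not corrupt eps and w
        Vx = V if V < Vpeak else Vpeak
        ex = (Vx - Vth) / DeltaT
        if ex > 20.0:
            ex = 20.0
        dV = (
            gL * (EL - V)
            + gL * DeltaT * ((e - epsc) / eps0) * exp(ex)
            - w
            + Itot
        ) / Cm
        de = ((1.0 - e / (alpha * eps0)) ** 3 - (Vx - Ef) / dEdF - w / gamma) / tau_e
        denom = epsc + 2.0 * (e if e > 0.0 else 0.0)
        katp = epsc / denom * IKATP if denom > 0.0 else 0.0
        dw = (a * (Vx - EL) - w + katp) / tau_w
        return dV, de, dw

    rk4 = method == "rk4"

    def step_elif(V, e, h, Itot, alpha):
        k1 = deriv_elif(V, e, Itot, alpha)
        if not rk4:
            return V + h * k1[0], e + h * k1[1]
        k2 = deriv_elif(V + 0.5 * h * k1[0], e + 0.5 * h * k1[1], Itot, alpha)
        k3 = deriv_elif(V + 0.5 * h * k2[0], e + 0.5 * h * k2[1], Itot, alpha)
        k4 = deriv_elif(V + h * k3[0], e + h * k3[1], Itot, alpha)
        return (
            V + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
            e + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
        )

    def step_madexp(V, e, w, h, Itot, alpha):
        k1 = deriv_madexp(V, e, w, Itot, alpha)
        if not rk4:
            return V + h * k1[0], e + h * k1[1], w + h * k1[2]
        k2 = deriv_madexp(
            V + 0.5 * h * k1[0], e + 0.5 * h * k1[1], w + 0.5 * h * k1[2],
            Itot, alpha,
        )
        k3 = deriv_madexp(
            V + 0.5 * h * k2[0], e + 0.5 * h * k2[1], w + 0.5 * h * k2[2],
            Itot, alpha,
        )
        k4 = deriv_madexp(
            V + h * k3[0], e + h * k3[1], w + h * k3[2], Itot, alpha
        )
        return (
            V + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
            e + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
            w + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
        )
    for n in range(n_steps):
        t_next = (n + 1) * dt
        if death_time is None:
            if alpha_arr is not None:
                alpha = alpha_arr[n]
            Itot = I_arr[n]
            if poisson is not None:
                if n_events is not None and n_events[n]:
                    if is_delta:
                        V += n_events[n] * pw / Cm
                    else:
                        I_syn += n_events[n] * pw
                if not is_delta:
                    Itot += I_syn
                    I_syn *= syn_decay

            in_refrac = t_next <= refrac_until
            if madexp:
                Vp, ep, wp = V, e, w
                V, e, w = step_madexp(V, e, w, h, Itot, alpha)
                if in_refrac:
                    V = Vr
                elif V >= Vpeak or V - Vp > _STEEP_DV:
                    # steep spike-initiation region: a full step under-
                    # resolves the exponential upswing, which would make the
                    # crossing state dt-dependent; redo the step in substeps
                    # and locate the crossing inside the substep it occurs in
                    V, e, w = Vp, ep, wp
                    hs = h / _N_SUB
                    for j in range(_N_SUB):
                        if n * dt + (j + 1) * hs <= refrac_until:
                            V, e, w = step_madexp(V, e, w, hs, Itot, alpha)
                            V = Vr
                            continue
                        Vq, eq, wq = V, e, w
                        V, e, w = step_madexp(V, e, w, hs, Itot, alpha)
                        if V >= Vpeak:
                            theta = (Vpeak - Vq) / (V - Vq) if V > Vq else 0.0
                            theta = min(max(theta, 0.0), 1.0)
                            t_spk = n * dt + (j + theta) * hs
                            spikes.append(t_spk)
                            V = Vr
                            e = eq + theta * (e - eq) - delta
                            w = wq + theta * (w - wq) + b
                            refrac_until = t_spk + refractory
                            rem = (1.0 - theta) * hs
                            if rem > 0.0:
                                V, e, w = step_madexp(V, e, w, rem, Itot, alpha)
                                if n * dt + (j + 1) * hs <= refrac_until:
                                    V = Vr
                if not (math.isfinite(V) and math.isfinite(e) and math.isfinite(w)):
                    raise IntegrationError(
                        f"non-finite state at step {n + 1} (t = {t_next:.3f} ms); "
                        "dt may be too large"
                    )
            else:
                Vp, ep = V, e
                V, e = step_elif(V, e, h, Itot, alpha)
                if in_refrac:
                    V = Vr
                if not (math.isfinite(V) and math.isfinite(e)):
                    raise IntegrationError(
                        f"non-finite state at step {n + 1} (t = {t_next:.3f} ms); "
                        "dt may be too large"
                    )
                if V >= Vth and e >= epsc and not in_refrac:
                    # the spike happens when the later of the two gating
                    # conditions (voltage, energy) becomes true in the step
                    if Vp >= Vth:
                        theta_v = 0.0
                    elif V > Vp:
                        theta_v = (Vth - Vp) / (V - Vp)
                    else:
                        theta_v = 1.0
                    if ep >= epsc:
                        theta_e = 0.0
                    elif e > ep:
                        theta_e = (epsc - ep) / (e - ep)
                    else:
                        theta_e = 1.0
                    theta = min(max(max(theta_v, theta_e), 0.0), 1.0)
                    t_spk = n * dt + theta * h
                    spikes.append(t_spk)
                    V = Vr
                    e = ep + theta * (e - ep) - delta
                    refrac_until = t_spk + refractory
                    rem = (1.0 - theta) * h
                    if rem > 0.0:
                        V, e = step_elif(V, e, rem, Itot, alpha)
                        if t_next <= refrac_until:
                            V = Vr
                        elif V >= Vth and e >= epsc:
                            spikes.append(t_next)
                            V, e = Vr, e - delta
                            refrac_until = t_next + refractory
            if e <= 0.0 and V >= Ed:
                death_time = t_next

        if (n + 1) % record_every == 0:
            t_out[rec_i] = t_next
            V_out[rec_i] = V
            e_out[rec_i] = e
            w_out[rec_i] = w
            rec_i += 1

    return SimulationResult(
        t=t_out[:rec_i],
        V=V_out[:rec_i],
        eps=e_out[:rec_i],
        w=w_out[:rec_i],
        spike_times=np.asarray(spikes),
        death_time=death_time,
        dt=dt,
        params=p,
    )


def detect_depolarization_block(
    result: SimulationResult,
    p: Optional[Params] = None,
    min_duration: float = 50.0,
) -> list[tuple[float, float]]:
    """Maximal intervals of superthreshold, energy-starved silence.

    An interval qualifies when ``V >= Vth`` and ``eps < epsc`` with no spike
    inside (for mAdExp the energy-suppressed exponential keeps such plateaus
    below ``Vpeak``).  Only intervals of at least ``min_duration`` ms are
    returned.
    """
    if p is None:
        p = result.params
    V, eps, t = result.V, result.eps, result.t
    mask = (V >= p.Vth) & (eps < p.epsc)

    # break candidate runs at spike times
    edges = np.concatenate(([0.0], result.spike_times, [t[-1] + result.dt]))
    intervals: list[tuple[float, float]] = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return intervals
    # contiguous runs of True
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    for i0, i1 in zip(starts, stops):
        t0, t1 = float(t[i0]), float(t[i1])
        # split on spikes falling inside
        inner = result.spike_times[
            (result.spike_times > t0) & (result.spike_times < t1)
        ]
        bounds = [t0, *inner.tolist(), t1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a >= min_duration:
                intervals.append((a, b))
    return intervals
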