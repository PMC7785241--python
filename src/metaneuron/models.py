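"""Core model definitions for the energy-constrained hybrid neuron models.

Two point-neuron models are defined here as pure functions of parameters and
state, with no integration logic:

* **eLIF** — a leaky integrate-and-fire neuron augmented with an energy
  variable ``eps`` (a phenomenological proxy for the ATP/ADP ratio).  Energy
  production relaxes ``eps`` toward the sustainable level ``alpha * eps0``
  while consumption grows with depolarization (a cubic nullcline shaped by the
  flex potential ``Ef`` and the depletion potential ``Ed``).  Spiking is gated
  by energy: a spike requires both ``V >= Vth`` and ``eps >= epsc``.

* **mAdExp** — an adaptive exponential integrate-and-fire neuron whose
  exponential spike-initiation term is scaled by ``(eps - epsc) / eps0`` (so
  spike generation shuts down as energy is depleted) and whose adaptation
  current ``w`` includes an ATP-sensitive potassium (K-ATP) term that grows
  as energy falls.

In both models the leak potential is energy dependent:
``EL(eps) = E0 + (Eu - E0) * (1 - eps / eps0)``, i.e. it equals ``Eu`` at zero
energy and crosses ``E0`` at ``eps = eps0``.  With ``Eu > E0`` (the integrator
regime) energy depletion depolarizes the cell, mimicking reduced Na/K-pump
activity.

Units: mV for potentials, pF for capacitance, nS for conductances, pA for
currents, ms for timescales; ``eps`` is dimensionless (presets use
``eps0 = 1``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Union

from .errors import InvalidStateError

__all__ = [
    "ELIFParams",
    "MAdExpParams",
    "NeuronState",
    "Params",
    "effective_leak",
    "elif_rhs",
    "madexp_rhs",
    "katp_current",
    "spike_condition",
    "apply_reset",
]

#: exponent clamp for the spike-initiation term (standard AdExp practice;
#: the voltage is cut at Vpeak anyway, this only guards intermediate stages)
_EXP_CLAMP = 20.0


@dataclass(frozen=True)
class ELIFParams:
    """Parameters of the energy-dependent leaky integrate-and-fire neuron.

    Attributes
    ----------
    Cm : float
        Membrane capacitance (pF).
    gL : float
        Leak conductance (nS).
    E0 : float
        Reference leak potential at ``eps = eps0`` (mV).
    Eu : float
        Leak potential at zero energy (mV).
    Ef : float
        Flex potential: inflection point of the energy nullcline (mV).
    Ed : float
        Energy-depletion potential: the lowest clamped potential that fully
        depletes the energy stock (mV); also the death potential.
    Vth : float
        Spike threshold (mV).
    Vr : float
        Reset potential (mV); must satisfy ``Vr < Vth``.
    eps0 : float
        Reference energy scale (dimensionless energy units).
    epsc : float
        Critical energy below which spike emission is impossible.
    alpha : float
        Energetic health in ``(0, 1]``; scales the sustainable energy level.
    tau_e : float
        Energy timescale (ms).
    delta : float
        Per-spike energy cost (energy units).
    Ie_baseline : float
        Constant applied current (pA).
    """

    Cm: float = 200.0
    gL: float = 10.0
    E0: float = -65.0
    Eu: float = -65.0
    Ef: float = -60.0
    Ed: float = -45.0
    Vth: float = -50.0
    Vr: float = -58.0
    eps0: float = 1.0
    epsc: float = 0.1
    alpha: float = 1.0
    tau_e: float = 300.0
    delta: float = 0.02
    Ie_baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Cm > 0):
            raise ValueError("Cm must be positive")
        if not (self.gL > 0):
            raise ValueError("gL must be positive")
        if not (self.tau_e > 0):
            raise ValueError("tau_e must be positive")
        if not (self.eps0 > 0):
            raise ValueError("eps0 must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.epsc < 0:
            raise ValueError("epsc must be non-negative")
        if self.Ed == self.Ef:
            raise ValueError("Ed must differ from Ef (non-degenerate energy nullcline)")
        if not isinstance(self, MAdExpParams) and not (self.Vr < self.Vth):
            # the hard eLIF threshold needs the reset below it; the mAdExp
            # reset may lie above Vth (burst-promoting) as long as it is
            # below the numerical cutoff, checked in the subclass
            raise ValueError("Vr must be below Vth")
        if self.Ed < self.Ef:
            warnings.warn(
                "Ed < Ef: energy consumption decreases with depolarization; "
                "default presets use Ed > Ef",
                stacklevel=2,
            )

    @property
    def tau_m(self) -> float:
        """Membrane timescale Cm / gL (ms)."""
        return self.Cm / self.gL

    def with_(self, **kwargs) -> "ELIFParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MAdExpParams(ELIFParams):
    """Parameters of the energy-modified adaptive exponential neuron.

    Extends :class:`ELIFParams` with the AdExp spike-initiation and adaptation
    machinery plus the K-ATP current.

    Attributes
    ----------
    DeltaT : float
        Spike slope factor (mV).
    Vpeak : float
        Numerical spike cutoff (mV); must exceed ``Vth``.
    a : float
        Subthreshold adaptation conductance (nS).
    b : float
        Spike-triggered adaptation increment (pA).
    tau_w : float
        Adaptation timescale (ms).
    gamma : float
        Adaptation-to-energy conversion; ``1 / gamma`` is the energetic cost
        per pA of adaptation current (the energy equation carries ``-w/gamma``).
    I_KATP : float
        Maximal K-ATP current at zero energy (pA).
    """

    DeltaT: float = 2.0
    Vpeak: float = 0.0
    a: float = 2.0
    b: float = 0.0
    tau_w: float = 30.0
    gamma: float = 1000.0
    I_KATP: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (self.DeltaT > 0):
            raise ValueError("DeltaT must be positive")
        if not (self.tau_w > 0):
            raise ValueError("tau_w must be positive")
        if not (self.gamma > 0):
            raise ValueError("gamma must be positive")
        if not (self.Vpeak > self.Vth):
            raise ValueError("Vpeak must exceed Vth")
        if not (self.Vr < self.Vpeak):
            raise ValueError("Vr must be below Vpeak")
        if self.b < 0:
            raise ValueError("b must be non-negative")
        if self.I_KATP < 0:
            raise ValueError("I_KATP must be non-negative")


Params = Union[ELIFParams, MAdExpParams]


@dataclass
class NeuronState:
    """Dynamical variables of a neuron at an instant.

    ``w`` is carried as a constant 0 for eLIF neurons so both models share one
    state type.  Once ``alive`` is False the state is frozen: integrators must
    not advance it further.
    """

    V: float
    eps: float
    w: float = 0.0
    alive: bool = True

    def copy(self) -> "NeuronState":
        return NeuronState(self.V, self.eps, self.w, self.alive)


def _is_madexp(p: Params) -> bool:
    return isinstance(p, MAdExpParams)


def effective_leak(eps: float, p: Params) -> float:
    """Energy-dependent leak potential ``E0 + (Eu - E0) * (1 - eps/eps0)``.

    Affine in ``eps``: equals ``Eu`` at zero energy and ``E0`` at
    ``eps = eps0``.  Accepts any real ``eps`` (the formula extrapolates).
    """
    return p.E0 + (p.Eu - p.E0) * (1.0 - eps / p.eps0)


def _check_state(s: NeuronState) -> None:
    if not (math.isfinite(s.V) and math.isfinite(s.eps) and math.isfinite(s.w)):
        raise InvalidStateError(
            f"non-finite state components: V={s.V}, eps={s.eps}, w={s.w}"
        )


def _eps_flow(V: float, eps: float, p: Params) -> float:
    """Smooth part of the energy flow (production minus voltage-driven cost),
    excluding the adaptation cost term and the 1/tau_e factor."""
    return (1.0 - eps / (p.alpha * p.eps0)) ** 3 - (V - p.Ef) / (p.Ed - p.Ef)


def elif_rhs(
    s: NeuronState, p: ELIFParams, I_syn: float = 0.0, I_e: float = 0.0
) -> tuple[float, float]:
    """Right-hand side of the eLIF continuous dynamics.

    Returns ``(dV/dt, deps/dt)`` in (mV/ms, energy/ms).  Valid wherever the
    continuous dynamics apply (``V < Vth`` or ``eps < epsc``); the function
    itself is defined for any finite state.
    """
    _check_state(s)
    dV = (p.gL * (effective_leak(s.eps, p) - s.V) + I_syn + I_e) / p.Cm
    deps = _eps_flow(s.V, s.eps, p) / p.tau_e
    return dV, deps


def katp_current(eps: float, p: MAdExpParams) -> float:
    """ATP-sensitive potassium current ``(epsc / (epsc + 2 eps)) * I_KATP``.

    Monotonically decreasing in ``eps``; equals ``I_KATP`` at zero energy and
    vanishes as ``eps`` grows.  With ``epsc = 0`` the term is identically 0
    for ``eps > 0`` (and defined as 0 at ``eps = 0`` as the continuous limit).
    """
    if p.epsc == 0.0:
        return 0.0
    return p.epsc / (p.epsc + 2.0 * eps) * p.I_KATP


def madexp_rhs(
    s: NeuronState, p: MAdExpParams, I_syn: float = 0.0, I_e: float = 0.0
) -> tuple[float, float, float]:
    """Right-hand side of the mAdExp continuous dynamics.

    Returns ``(dV/dt, deps/dt, dw/dt)``.  The exponential spike-initiation
    term is scaled by ``(eps - epsc)/eps0`` so it vanishes at ``eps = epsc``
    and reverses (hyperpolarizing) below it; its exponent is clamped to avoid
    overflow before the ``Vpeak`` cutoff applies.
    """
    _check_state(s)
    EL = effective_leak(s.eps, p)
    # beyond the numerical cutoff the trajectory is unphysical (the spike is
    # about to be detected and reset); cap the voltage seen by the coupled
    # equations at Vpeak so a steep upswing cannot corrupt eps and w
    Vx = s.V if s.V < p.Vpeak else p.Vpeak
    expo = (Vx - p.Vth) / p.DeltaT
    if expo > _EXP_CLAMP:
        expo = _EXP_CLAMP
    I_exp = p.gL * p.DeltaT * ((s.eps - p.epsc) / p.eps0) * math.exp(expo)
    dV = (p.gL * (EL - s.V) + I_exp - s.w + I_syn + I_e) / p.Cm
    deps = (_eps_flow(Vx, s.eps, p) - s.w / p.gamma) / p.tau_e
    dw = (p.a * (Vx - EL) - s.w + katp_current(s.eps, p)) / p.tau_w
    return dV, deps, dw


def spike_condition(s: NeuronState, p: Params) -> bool:
    """Whether the hybrid spike/reset rule fires in the current state.

    eLIF: ``V >= Vth`` *and* ``eps >= epsc`` (a superthreshold neuron with
    depleted energy does not spike — that is the depolarization block).
    mAdExp: ``V >= Vpeak`` (energy gating is implicit in the suppressed
    exponential).  Ties at ``eps = epsc`` count as spiking.
    """
    if _is_madexp(p):
        return s.V >= p.Vpeak
    return s.V >= p.Vth and s.eps >= p.epsc


def apply_reset(s: NeuronState, p: Params) -> NeuronState:
    """Post-spike reset: ``V <- Vr``, ``eps <- eps - delta`` and, for mAdExp,
    ``w <- w + b``.  ``eps`` may transiently go negative; viability is the
    integrator's responsibility, not the reset's."""
    w = s.w + p.b if _is_madexp(p) else s.w
    return NeuronState(V=p.Vr, eps=s.eps - p.delta, w=w, alive=s.alive)
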