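"""Phase-plane and bifurcation analysis.

For the eLIF model the fixed points of the smooth flow are the intersections
of two nullclines in the (eps, V) plane:

* V-nullcline:   ``V = EL(eps) + I/gL``   (a line, shifted by the current)
* eps-nullcline: ``V = Ef + (Ed - Ef) * (1 - eps/(alpha eps0))**3`` (a cubic)

Depending on parameters and applied current the biophysical window
(``eps >= 0``) contains zero, one, or three fixed points.  Three fixed points
mean a bistable cell with distinct up- (low energy, depolarized) and down-
(high energy, hyperpolarized) states; the boundary of the bistable current
interval is a pair of saddle-node bifurcations whose currents are computed
here by a numerical tangency solver (and cross-checked against the closed
form in the test-suite).

mAdExp fixed points are solved on the full 3-D system; a fast path seeds the
3-D root-finder from the eLIF 2-D approximation, which is accurate for
standard resting states where the adaptation current is near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import MetaNeuronError
from .models import (
    ELIFParams,
    MAdExpParams,
    NeuronState,
    Params,
    effective_leak,
    elif_rhs,
    katp_current,
    madexp_rhs,
)

__all__ = [
    "FixedPoint",
    "PhasePortrait",
    "SaddleNodeResult",
    "v_nullcline",
    "eps_nullcline",
    "find_fixed_points",
    "saddle_node_currents",
    "saddle_node_closed_form",
    "rebound_threshold",
    "classify_regime",
    "alpha_sweep",
    "if_curve",
]

#: tolerance on eigenvalue real parts when labelling stability
_STAB_TOL = 1e-9


@dataclass(frozen=True)
class FixedPoint:
    """A fixed point of the smooth flow, with linear stability."""

    V: float
    eps: float
    w: float = 0.0
    stability: str = "stable"  # one of {"stable", "unstable", "saddle"}
    marginal: bool = False
    in_continuous_region: bool = True

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class SaddleNodeResult:
    """The two saddle-node bifurcation currents bounding the bistable regime.

    When no real tangency exists (e.g. ``Eu = E0``) both currents collapse to
    ``gL * (Ef - Eu + alpha (Eu - E0))`` and ``degenerate`` is set.
    """

    I_minus: float
    I_plus: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.I_minus, self.I_plus))


@dataclass(frozen=True)
class PhasePortrait:
    """Sampled nullclines plus the fixed-point list at a given current."""

    eps_grid: np.ndarray
    v_null: np.ndarray
    eps_null: np.ndarray
    fixed_points: tuple[FixedPoint, ...]
    I_total: float
    params: Params


def v_nullcline(eps, p: Params, I_total: float = 0.0):
    """Voltage nullcline ``V = EL(eps) + I/gL`` (vectorized in ``eps``)."""
    return effective_leak(np.asarray(eps, dtype=float), p) + I_total / p.gL


def eps_nullcline(eps, p: Params):
    """Energy nullcline ``V = Ef + (Ed - Ef)(1 - eps/(alpha eps0))**3``."""
    u = 1.0 - np.asarray(eps, dtype=float) / (p.alpha * p.eps0)
    return p.Ef + (p.Ed - p.Ef) * u**3


def _elif_jacobian(V: float, eps: float, p: ELIFParams) -> np.ndarray:
    u = 1.0 - eps / (p.alpha * p.eps0)
    return np.array(
        [
            [-p.gL / p.Cm, -p.gL * (p.Eu - p.E0) / (p.eps0 * p.Cm)],
            [
                -1.0 / ((p.Ed - p.Ef) * p.tau_e),
                -3.0 * u**2 / (p.alpha * p.eps0 * p.tau_e),
            ],
        ]
    )


def _madexp_jacobian(V: float, eps: float, w: float, p: MAdExpParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of the mAdExp smooth flow (below the clamp)."""
    u = 1.0 - eps / (p.alpha * p.eps0)
    dEL_deps = -(p.Eu - p.E0) / p.eps0
    e = math.exp((V - p.Vth) / p.DeltaT)
    fac = (eps - p.epsc) / p.eps0
    # dV/dt row
    dVdV = (-p.gL + p.gL * fac * e) / p.Cm
    dVde = (p.gL * dEL_deps + p.gL * p.DeltaT * e / p.eps0) / p.Cm
    dVdw = -1.0 / p.Cm
    # deps/dt row
    dedV = -1.0 / ((p.Ed - p.Ef) * p.tau_e)
    dede = -3.0 * u**2 / (p.alpha * p.eps0 * p.tau_e)
    dedw = -1.0 / (p.gamma * p.tau_e)
    # dw/dt row
    if p.epsc > 0:
        dkatp = -2.0 * p.epsc * p.I_KATP / (p.epsc + 2.0 * eps) ** 2
    else:
        dkatp = 0.0
    dwdV = p.a / p.tau_w
    dwde = (-p.a * dEL_deps + dkatp) / p.tau_w
    dwdw = -1.0 / p.tau_w
    return np.array([[dVdV, dVde, dVdw], [dedV, dede, dedw], [dwdV, dwde, dwdw]])


def _label_stability(J: np.ndarray) -> tuple[str, bool]:
    lam = np.linalg.eigvals(J)
    re = np.real(lam)
    marginal = bool(np.any(np.abs(re) <= _STAB_TOL))
    if np.all(re < -_STAB_TOL):
        return "stable", marginal
    if np.any(re > _STAB_TOL) and np.any(re < -_STAB_TOL):
        return "saddle", marginal
    return "unstable", marginal


def _continuous_region(V: float, eps: float, p: Params) -> bool:
    if isinstance(p, MAdExpParams):
        return V < p.Vpeak
    return (V < p.Vth) or (eps < p.epsc)


def _elif_fixed_points(
    p: ELIFParams, I_total: float, eps_window: tuple[float, float], n_grid: int
) -> list[FixedPoint]:
    lo, hi = eps_window
    grid = np.linspace(lo, hi, n_grid)
    diff = v_nullcline(grid, p, I_total) - eps_nullcline(grid, p)

    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            f = lambda e: float(
                v_nullcline(e, p, I_total) - eps_nullcline(e, p)
            )
            # brentq on V-difference; xtol far below the 1e-10 mV contract
            roots.append(float(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-13)))
    if diff[-1] == 0.0:
        roots.append(float(grid[-1]))

    fps = []
    for eps in roots:
        if eps < 0:
            continue  # biophysically unacceptable
        V = float(v_nullcline(eps, p, I_total))
        stab, marginal = _label_stability(_elif_jacobian(V, eps, p))
        fps.append(
            FixedPoint(
                V=V,
                eps=eps,
                w=0.0,
                stability=stab,
                marginal=marginal,
                in_continuous_region=_continuous_region(V, eps, p),
            )
        )
    fps.sort(key=lambda f: f.eps)
    return fps


def _madexp_system(x: np.ndarray, p: MAdExpParams, I_total: float) -> np.ndarray:
    s = NeuronState(V=float(x[0]), eps=float(x[1]), w=float(x[2]))
    return np.array(madexp_rhs(s, p, 0.0, I_total))


def _madexp_fixed_points(
    p: MAdExpParams, I_total: float, eps_window: tuple[float, float], n_grid: int
) -> list[FixedPoint]:
    # Seed the 3-D root-finder from the eLIF 2-D approximation (valid for
    # resting states where w is small) plus a coarse grid of extra seeds.
    elif_p = ELIFParams(
        Cm=p.Cm, gL=p.gL, E0=p.E0, Eu=p.Eu, Ef=p.Ef, Ed=p.Ed, Vth=p.Vth,
        # Vr plays no role in the fixed-point structure; clamp it below the
        # threshold to satisfy the eLIF invariant (mAdExp allows Vr >= Vth)
        Vr=min(p.Vr, p.Vth - 1.0), eps0=p.eps0, epsc=p.epsc, alpha=p.alpha,
        tau_e=p.tau_e, delta=p.delta, Ie_baseline=p.Ie_baseline,
    )
    seeds = [
        (fp.V, fp.eps, 0.0)
        for fp in _elif_fixed_points(elif_p, I_total, eps_window, n_grid)
    ]
    lo, hi = eps_window
    for eps in np.linspace(max(lo, 1e-3), hi, 7):
        V = float(eps_nullcline(eps, p))
        w0 = p.a * (V - effective_leak(eps, p)) + katp_current(eps, p)
        seeds.append((V, float(eps), w0))

    found: list[FixedPoint] = []
    for seed in seeds:
        sol = optimize.root(
            _madexp_system, np.array(seed), args=(p, I_total), method="hybr",
            options={"xtol": 1e-12},
        )
        if not sol.success:
            continue
        V, eps, w = (float(v) for v in sol.x)
        if not (lo - 1e-9 <= eps <= hi + 1e-9) or eps < 0:
            continue
        if max(abs(r) for r in _madexp_system(sol.x, p, I_total)) > 1e-8:
            continue
        if any(abs(eps - f.eps) < 1e-6 and abs(V - f.V) < 1e-6 for f in found):
            continue
        stab, marginal = _label_stability(_madexp_jacobian(V, eps, w, p))
        found.append(
            FixedPoint(
                V=V, eps=eps, w=w, stability=stab, marginal=marginal,
                in_continuous_region=_continuous_region(V, eps, p),
            )
        )
    found.sort(key=lambda f: f.eps)
    return found


def find_fixed_points(
    p: Params,
    I_total: float = 0.0,
    eps_window: Optional[tuple[float, float]] = None,
    n_grid: int = 2001,
) -> list[FixedPoint]:
    """All fixed points of the smooth flow with ``eps`` in ``eps_window``.

    The default window is ``[0, 2 eps0]``; fixed points with ``eps < 0`` are
    discarded as biophysically unacceptable.  An empty list means the neuron
    has no sustainable steady state (the "nonviable" regime).
    """
    if eps_window is None:
        eps_window = (0.0, 2.0 * p.eps0)
    if isinstance(p, MAdExpParams):
        return _madexp_fixed_points(p, I_total, eps_window, n_grid)
    return _elif_fixed_points(p, I_total, eps_window, n_grid)


def phase_portrait(
    p: Params,
    I_total: float = 0.0,
    eps_window: Optional[tuple[float, float]] = None,
    n_grid: int = 401,
) -> PhasePortrait:
    """Sample both nullclines and locate the fixed points."""
    if eps_window is None:
        eps_window = (0.0, 2.0 * p.eps0)
    grid = np.linspace(eps_window[0], eps_window[1], n_grid)
    return PhasePortrait(
        eps_grid=grid,
        v_null=v_nullcline(grid, p, I_total),
        eps_null=eps_nullcline(grid, p),
        fixed_points=tuple(find_fixed_points(p, I_total, eps_window)),
        I_total=I_total,
        params=p,
    )


def saddle_node_closed_form(p: ELIFParams) -> SaddleNodeResult:
    """Closed-form saddle-node currents (cross-check for the numerical solver).

    ``I± = gL [Ef - Eu + alpha (Eu - E0) (1 ± (2/3) sqrt(alpha (Eu - E0) /
    (3 (Ed - Ef))))]`` — derived from the tangency of the two nullclines.
    """
    B = p.alpha * (p.Eu - p.E0)
    A = p.Ed - p.Ef
    base = p.gL * (p.Ef - p.Eu + B)
    if B / A <= 0.0 or B == 0.0:
        return SaddleNodeResult(base, base, degenerate=True)
    ustar = math.sqrt(B / (3.0 * A))
    lo = p.gL * (p.Ef - p.Eu + B * (1.0 - 2.0 / 3.0 * ustar))
    hi = p.gL * (p.Ef - p.Eu + B * (1.0 + 2.0 / 3.0 * ustar))
    return SaddleNodeResult(min(lo, hi), max(lo, hi), degenerate=False)


def saddle_node_currents(p: ELIFParams) -> SaddleNodeResult:
    """Saddle-node bifurcation currents via a numerical tangency solver.

    A saddle-node occurs where the nullcline difference and its eps-derivative
    vanish simultaneously.  The derivative is solved by bracketed 1-D
    root-finding; the current then follows from the difference equation
    (the V-nullcline shifts affinely with ``I/gL``).  This numerical route is
    the authoritative output; the closed form is exposed separately for
    cross-checking.
    """

    def dderiv(eps: float) -> float:
        # d/deps [v_nullcline - eps_nullcline]  (I-independent)
        u = 1.0 - eps / (p.alpha * p.eps0)
        return -(p.Eu - p.E0) / p.eps0 + 3.0 * (p.Ed - p.Ef) * u**2 / (
            p.alpha * p.eps0
        )

    base = p.gL * (p.Ef - p.Eu + p.alpha * (p.Eu - p.E0))
    B = p.alpha * (p.Eu - p.E0)
    A = p.Ed - p.Ef
    if B == 0.0 or B / A <= 0.0:
        return SaddleNodeResult(base, base, degenerate=True)

    # Tangency eps values bracket the inflection point eps = alpha*eps0 where
    # the derivative of the cubic term vanishes.
    e_infl = p.alpha * p.eps0
    half_width = p.alpha * p.eps0  # search each side over one alpha*eps0 span
    currents = []
    for lo, hi in ((e_infl - half_width, e_infl), (e_infl, e_infl + half_width)):
        flo, fhi = dderiv(lo), dderiv(hi)
        if flo * fhi > 0:
            continue
        estar = optimize.brentq(dderiv, lo, hi, xtol=1e-13)
        # difference(eps*, I) = 0  =>  I = gL * (eps_null - EL)(eps*)
        I = p.gL * (float(eps_nullcline(estar, p)) - effective_leak(estar, p))
        currents.append(I)
    if len(currents) < 2:
        return SaddleNodeResult(base, base, degenerate=True)
    return SaddleNodeResult(min(currents), max(currents), degenerate=False)


def rebound_threshold(p: MAdExpParams) -> Optional[tuple[float, bool]]:
    """Divergence potential ``V* = Vth + DeltaT ln((Eu - E0)/DeltaT)``.

    With ``Eu > E0`` the energy-dependent leak makes the V-nullcline of the
    mAdExp model diverge upward before threshold, creating a stable fixed
    point above ``V*`` that supports rebound spiking without a sag.  Returns
    ``(V_star, applicable)`` where ``applicable`` is True iff
    ``Eu - E0 < DeltaT`` (then ``V* < Vth``); returns None if ``Eu <= E0``.
    """
    d = p.Eu - p.E0
    if d <= 0.0:
        return None
    v_star = p.Vth + p.DeltaT * math.log(d / p.DeltaT)
    return v_star, d < p.DeltaT


def classify_regime(
    p: Params,
    I_total: float = 0.0,
    eps_window: Optional[tuple[float, float]] = None,
) -> str:
    """Regime label from the fixed-point structure.

    ``bistable`` (3 FPs), ``single-rest`` (1 FP below threshold),
    ``tonic-spiking`` (1 superthreshold FP with enough energy),
    ``energy-blocked`` (1 superthreshold FP starved of energy) or
    ``nonviable`` (no FP in the biophysical window).
    """
    fps = find_fixed_points(p, I_total, eps_window)
    if len(fps) == 0:
        return "nonviable"
    if len(fps) >= 3:
        return "bistable"
    fp = fps[0]
    if fp.V < p.Vth:
        return "single-rest"
    if fp.eps > p.epsc:
        return "tonic-spiking"
    return "energy-blocked"


def alpha_sweep(
    p: Params,
    alpha_grid: Sequence[float],
    I_total: float = 0.0,
    eps_window: Optional[tuple[float, float]] = None,
) -> tuple[list[tuple[float, list[FixedPoint], str]], list[str]]:
    """Evaluate the fixed-point structure along a grid of health values.

    Returns ``(rows, stages)`` where each row is
    ``(alpha, fixed_points, regime)`` and ``stages`` is the compressed stage
    sequence (consecutive duplicate regimes merged) — the disease-progression
    staging of a health-to-disease sweep.
    """
    rows = []
    for a in alpha_grid:
        if not (0.0 < a <= 1.0):
            raise ValueError("alpha_grid values must lie in (0, 1]")
        pa = replace(p, alpha=float(a))
        fps = find_fixed_points(pa, I_total, eps_window)
        rows.append((float(a), fps, classify_regime(pa, I_total, eps_window)))
    stages: list[str] = []
    for _, _, regime in rows:
        if not stages or stages[-1] != regime:
            stages.append(regime)
    return rows, stages


def if_curve(
    p: Params,
    I_grid: Sequence[float],
    T: Optional[float] = None,
    dt: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Steady-state firing rate (Hz) for each applied current.

    Each current is applied for ``T`` ms (default ``10 tau_e``, at least
    ``5 tau_e`` to approach stationarity) and the rate is measured from spikes
    in the last half of the run.
    """
    from .simulate import Protocol, integrate  # local import to avoid a cycle

    if T is None:
        T = 10.0 * p.tau_e
    if T < 5.0 * p.tau_e:
        raise ValueError("T must be at least 5 * tau_e for a steady-state rate")
    rates = []
    for I in I_grid:
        proto = Protocol(duration=T, segments=[(0.0, T, float(I))])
        res = integrate(p, None, proto, dt=dt, seed=seed)
        n = int(np.sum(np.asarray(res.spike_times) >= T / 2.0))
        rates.append(n / (T / 2.0) * 1000.0)
    return np.asarray(rates)
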