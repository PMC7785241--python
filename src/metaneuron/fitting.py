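"""Subthreshold feature extraction and a trace-discrepancy score.

The estimators implement the standard current-clamp characterization used to
constrain the passive parameters of the models:

* :func:`estimate_EL` — median resting potential over baseline windows.
* :func:`estimate_tau_m` — membrane timescale from the initial slope of the
  response to hyperpolarizing steps (``tau_m = dV_ss / (dV/dt at onset)``).
* :func:`estimate_gL_plus_a` — reciprocal slope of the steady-state
  deflection against injected current, ``dV = I / (a + gL)``; for a model
  without subthreshold adaptation this is simply ``gL``.

:func:`discrepancy` scores a simulated trace against a target sweep
(subthreshold RMSE with spikes masked, spike-count and spike-time terms) so
that any external optimizer can be driven with it.  Automated optimization of
the full parameter set is deliberately out of scope: only the constraint
extraction is automated, everything else is meant to be adjusted by hand or
by user-supplied search loops.

Note that the resting potential constrains only the *effective* leak
``EL = E0 + (Eu - E0)(1 - eps_rest/eps0)``; the split between ``E0`` and
``Eu`` is not identifiable from subthreshold data alone and is reported as a
single ``EL_hat`` value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .simulate import SimulationResult

__all__ = [
    "Sweep",
    "SweepSet",
    "SubthresholdFeatures",
    "estimate_EL",
    "estimate_tau_m",
    "estimate_gL_plus_a",
    "extract_subthreshold_features",
    "discrepancy",
    "read_sweep_file",
]


@dataclass(frozen=True)
class Sweep:
    """One current-clamp sweep at uniform sampling.

    ``t`` in ms, ``V`` in mV; ``I`` is the step amplitude in pA applied
    during ``[step_start, step_stop)``; outside that window the injected
    current is zero (the baseline).
    """

    t: np.ndarray
    V: np.ndarray
    I: float
    step_start: float
    step_stop: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "V", V)
        if t.ndim != 1 or V.shape != t.shape or t.size < 4:
            raise ConfigError("sweep: t and V must be 1-D arrays of equal length >= 4")
        dts = np.diff(t)
        if not np.all(dts > 0):
            raise ConfigError("sweep: time must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ConfigError("sweep: sampling must be uniform")
        if not (self.step_start < self.step_stop):
            raise ConfigError("sweep: step_start must precede step_stop")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def baseline_mask(self) -> np.ndarray:
        """Samples outside the stimulation window (plus one membrane-settle
        guard of 50 ms after the step offset)."""
        return (self.t < self.step_start) | (self.t >= self.step_stop + 50.0)

    def steady_state(self, fraction: float = 0.2) -> float:
        """Mean voltage over the last ``fraction`` of the step window."""
        t0 = self.step_stop - fraction * (self.step_stop - self.step_start)
        m = (self.t >= t0) & (self.t < self.step_stop)
        if not m.any():
            raise ConfigError("sweep: no samples in the steady-state window")
        return float(np.mean(self.V[m]))


@dataclass(frozen=True)
class SweepSet:
    """A collection of sweeps from one cell."""

    sweeps: tuple[Sweep, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sweeps", tuple(self.sweeps))
        if not self.sweeps:
            raise ConfigError("sweep set: at least one sweep is required")

    def hyperpolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.I < 0]

    def depolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.I > 0]


@dataclass(frozen=True)
class SubthresholdFeatures:
    """Passive-property estimates extracted from a sweep set."""

    EL_hat: float  # mV
    tau_m_hat: Optional[float]  # ms (None if no usable hyperpolarizing sweep)
    gL_plus_a_hat: Optional[float]  # nS (None if fewer than 2 distinct currents)
    deflections: dict = field(default_factory=dict)  # I (pA) -> dV_ss (mV)

    def __post_init__(self) -> None:
        if self.tau_m_hat is not None and not (self.tau_m_hat > 0):
            raise ConfigError("features: tau_m_hat must be positive")
        if self.gL_plus_a_hat is not None and not (self.gL_plus_a_hat > 0):
            raise ConfigError("features: gL_plus_a_hat must be positive")


def estimate_EL(sweeps: SweepSet) -> float:
    """Median voltage pooled over all baseline windows (mV).

    The median makes the estimate robust to symmetric noise and to brief
    artifacts in the baseline.
    """
    pooled = []
    for s in sweeps.sweeps:
        m = s.baseline_mask()
        if m.any():
            pooled.append(s.V[m])
    if not pooled:
        raise ConfigError("estimate_EL: no baseline samples in any sweep")
    return float(np.median(np.concatenate(pooled)))


def _initial_slope(s: Sweep, window: Optional[float]) -> Optional[float]:
    """Linear-fit slope of V(t) over the onset window of the step (mV/ms).

    Returns None (with a warning) when the onset is noise-dominated, i.e.
    the fitted slope does not have the sign of the applied current.
    """
    if window is None:
        window = max(5.0, 0.05 * (s.step_stop - s.step_start))
    m = (s.t >= s.step_start) & (s.t < s.step_start + window)
    if m.sum() < 2:
        warnings.warn("onset window contains fewer than 2 samples", stacklevel=3)
        return None
    slope = float(np.polyfit(s.t[m], s.V[m], 1)[0])
    if slope * np.sign(s.I) <= 0:
        warnings.warn(
            "non-monotonic step onset (noise-dominated); sweep skipped",
            stacklevel=3,
        )
        return None
    return slope


def _profiled_rc_sse(
    data: list[tuple[np.ndarray, np.ndarray, float]], tau: float
) -> tuple[float, float]:
    """Residual of the shared RC model at a fixed ``tau``.

    Model per sweep: ``V(t) - v0 = c_s + (I_s / g) (1 - exp(-t/tau))`` with a
    free offset ``c_s`` per sweep and one shared conductance ``g``.  For a
    fixed ``tau`` the offsets and the slope ``1/g`` are linear and profiled
    out in closed form.  Returns ``(sse, slope)``.
    """
    num = den = 0.0
    parts = []
    for trel, meas, amp in data:
        gf = amp * (1.0 - np.exp(-trel / tau))
        gc = gf - gf.mean()
        mc = meas - meas.mean()
        parts.append((gc, mc))
        num += float(np.sum(gc * mc))
        den += float(np.sum(gc * gc))
    slope = num / den if den > 0 else 0.0
    sse = sum(float(np.sum((mc - slope * gc) ** 2)) for gc, mc in parts)
    return sse, slope


def estimate_tau_m(
    sweeps: SweepSet, onset_window: Optional[float] = None
) -> float:
    """Effective membrane time constant (ms).

    All nonzero-current subthreshold sweeps are fitted jointly with the
    shared RC model ``V(t) = v0 + c_s + (I_s / g)(1 - exp(-t/tau))`` over the
    full step window (free offset per sweep, one shared conductance, one
    shared ``tau``); the linear parameters are profiled out and ``tau`` is
    found by a log-grid scan with golden-section refinement.  For a pure RC
    response this returns ``Cm / gL`` exactly; for a cell with fast
    subthreshold adaptation it returns the effective constant
    ``Cm / (gL + a)``, consistent with :func:`estimate_gL_plus_a`.

    Each sweep's onset is first sanity-checked with a linear fit over
    ``onset_window`` (default: the first ``max(5 ms, 5 %)`` of the step);
    noise-dominated sweeps whose onset slope contradicts the sign of the
    current are skipped with a warning.  At least one usable hyperpolarizing
    sweep is required.
    """
    data = []
    has_hyper = False
    for s in sweeps.sweeps:
        if s.I == 0:
            continue
        window = onset_window
        if window is None:
            window = max(5.0, 0.05 * (s.step_stop - s.step_start))
        if _initial_slope(s, window) is None:
            continue
        m = (s.t >= s.step_start) & (s.t < s.step_stop)
        if m.sum() < 4:
            continue
        trel = s.t[m] - s.step_start
        baseline = s.V[s.t < s.step_start]
        v0 = float(np.median(baseline)) if baseline.size else float(s.V[0])
        data.append((trel, s.V[m] - v0, s.I))
        has_hyper = has_hyper or s.I < 0
    if not has_hyper:
        raise ConfigError("estimate_tau_m: no usable hyperpolarizing sweep")

    grid = np.geomspace(0.1, 1e3, 400)
    errs = [_profiled_rc_sse(data, g)[0] for g in grid]
    k = int(np.argmin(errs))
    lo = np.log(grid[max(k - 1, 0)])
    hi = np.log(grid[min(k + 1, grid.size - 1)])
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a_, b_ = lo, hi
    c_, d_ = b_ - phi * (b_ - a_), a_ + phi * (b_ - a_)
    fc = _profiled_rc_sse(data, float(np.exp(c_)))[0]
    fd = _profiled_rc_sse(data, float(np.exp(d_)))[0]
    for _ in range(80):
        if fc < fd:
            b_, d_, fd = d_, c_, fc
            c_ = b_ - phi * (b_ - a_)
            fc = _profiled_rc_sse(data, float(np.exp(c_)))[0]
        else:
            a_, c_, fc = c_, d_, fd
            d_ = a_ + phi * (b_ - a_)
            fd = _profiled_rc_sse(data, float(np.exp(d_)))[0]
    tau = float(np.exp((a_ + b_) / 2.0))
    _, slope = _profiled_rc_sse(data, tau)
    if slope <= 0:
        raise ConfigError(
            "estimate_tau_m: non-positive fitted conductance slope "
            "(sweeps are not passive subthreshold responses)"
        )
    return tau


def estimate_gL_plus_a(sweeps: SweepSet) -> float:
    """Total subthreshold conductance ``a + gL`` (nS).

    Least-squares slope of the steady-state deflection ``dV = E_ss - E_L``
    against the injected current gives ``1/(a + gL)``; the reciprocal is
    returned.  All subthreshold sweeps (both polarities) contribute.
    """
    EL = estimate_EL(sweeps)
    Is, dVs = [], []
    for s in sweeps.sweeps:
        if s.I == 0:
            continue
        Is.append(s.I)
        dVs.append(s.steady_state() - EL)
    if len(set(Is)) < 2:
        raise ConfigError(
            "estimate_gL_plus_a: need at least two sweeps with distinct "
            "nonzero currents"
        )
    Is_arr = np.asarray(Is)
    dVs_arr = np.asarray(dVs)
    # slope through the origin is the model relation; keep an intercept to
    # absorb a small EL bias, the slope is what matters
    slope = float(np.polyfit(Is_arr, dVs_arr, 1)[0])
    if slope <= 0:
        raise ConfigError(
            "estimate_gL_plus_a: non-positive regression slope "
            "(sweeps are not passive subthreshold responses)"
        )
    return 1.0 / slope


def extract_subthreshold_features(
    sweeps: SweepSet, onset_window: Optional[float] = None
) -> SubthresholdFeatures:
    """Run all three estimators, tolerating partially usable sweep sets."""
    EL = estimate_EL(sweeps)
    try:
        tau = estimate_tau_m(sweeps, onset_window)
    except ConfigError:
        tau = None
    try:
        g = estimate_gL_plus_a(sweeps)
    except ConfigError:
        g = None
    deflections = {
        float(s.I): s.steady_state() - EL for s in sweeps.sweeps if s.I != 0
    }
    return SubthresholdFeatures(
        EL_hat=EL, tau_m_hat=tau, gL_plus_a_hat=g, deflections=deflections
    )


def _mask_spikes(t: np.ndarray, spikes: Sequence[float], pad: float) -> np.ndarray:
    keep = np.ones_like(t, dtype=bool)
    for ts in spikes:
        keep &= np.abs(t - ts) > pad
    return keep


def discrepancy(
    result: SimulationResult,
    target_t: np.ndarray,
    target_V: np.ndarray,
    target_spikes: Sequence[float] = (),
    w_rmse: float = 1.0,
    w_count: float = 10.0,
    w_time: float = 0.1,
    spike_pad: float = 5.0,
    max_time_diff: float = 50.0,
) -> float:
    """Weighted discrepancy between a simulation and a target trace.

    Terms (defaults): 1 per mV of subthreshold RMSE with spikes masked
    +- ``spike_pad`` ms on both sides, 10 per spike of absolute spike-count
    difference, and 0.1 per ms of mean absolute matched spike-time
    difference (greedy nearest matching, individual differences capped at
    ``max_time_diff``).  Zero when a result is compared with itself.
    """
    target_t = np.asarray(target_t, dtype=float)
    target_V = np.asarray(target_V, dtype=float)
    V_model = np.interp(target_t, result.t, result.V)
    all_spikes = list(result.spike_times) + list(target_spikes)
    keep = _mask_spikes(target_t, all_spikes, spike_pad)
    if keep.any():
        rmse = float(np.sqrt(np.mean((V_model[keep] - target_V[keep]) ** 2)))
    else:
        rmse = 0.0

    model_spikes = list(result.spike_times)
    tgt = list(target_spikes)
    count_term = abs(len(model_spikes) - len(tgt))

    # greedy nearest matching on the shorter list
    diffs = []
    pool = sorted(tgt)
    for ts in sorted(model_spikes):
        if not pool:
            break
        j = int(np.argmin([abs(ts - u) for u in pool]))
        diffs.append(min(abs(ts - pool[j]), max_time_diff))
        pool.pop(j)
    time_term = float(np.mean(diffs)) if diffs else 0.0

    return w_rmse * rmse + w_count * count_term + w_time * time_term


def read_sweep_file(path) -> SweepSet:
    """Parse a plain-text current-clamp sweep file into a :class:`SweepSet`.

    The file holds whitespace-separated columns, either ``(t_ms, V_mV,
    I_pA)`` for a single sweep or ``(sweep_id, t_ms, V_mV, I_pA)`` for
    several sweeps in one file.  The ``I_pA`` column is the injected current
    at each sample.  Lines starting with ``#`` are metadata; the step window
    must be declared in two of them::

        # step_start_ms = 100.0
        # step_stop_ms = 500.0

    Each sweep's step amplitude is taken as the median of its current column
    inside the window.  Raises :class:`~metaneuron.errors.ConfigError` on
    malformed files.
    """
    from pathlib import Path

    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read sweep file {path}: {exc}") from exc
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        try:
            rows.append([float(x) for x in line.split()])
        except ValueError as exc:
            raise ConfigError(f"{path}:{ln}: non-numeric data: {line!r}") from exc
    if not rows:
        raise ConfigError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if widths not in ({3}, {4}):
        raise ConfigError(
            f"{path}: expected 3 columns (t, V, I) or 4 columns "
            f"(sweep, t, V, I); got widths {sorted(widths)}"
        )
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] == 3:
        arr = np.column_stack([np.zeros(len(arr)), arr])
    try:
        start = float(meta["step_start_ms"])
        stop = float(meta["step_stop_ms"])
    except KeyError as exc:
        raise ConfigError(
            f"{path}: missing '# step_start_ms = ...' / "
            f"'# step_stop_ms = ...' header line"
        ) from exc
    sweeps = []
    for sid in np.unique(arr[:, 0]):
        sub = arr[arr[:, 0] == sid]
        t, V, I = sub[:, 1], sub[:, 2], sub[:, 3]
        inside = (t >= start) & (t < stop)
        amp = float(np.median(I[inside])) if inside.any() else 0.0
        try:
            sweeps.append(
                Sweep(t=t, V=V, I=amp, step_start=start, step_stop=stop)
            )
        except ConfigError as exc:
            raise ConfigError(f"{path}: sweep {int(sid)}: {exc}") from exc
    return SweepSet(tuple(sweeps))
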