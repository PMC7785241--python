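"""Recurrent E/I networks of energy-constrained neurons.

A sparse random directed network of eLIF (or mAdExp) neurons with
current-based exponential synapses, independent per-neuron Poisson background
drive, an optional stimulus window (rate multiplier on a target subset), and
a homeostasis table that maps an energetic-health level ``alpha`` to the
compensating excitability/weight adjustments (synaptic scaling plus threshold
and reset shifts) that keep the background firing statistics stable as health
declines.

The update is synchronous and clock-driven (vectorized RK4 on the smooth
flow, end-of-step spike check) with spike delivery delayed through a ring
buffer.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .models import ELIFParams, MAdExpParams, Params, effective_leak

__all__ = [
    "HomeostasisEntry",
    "StimulusSpec",
    "NetworkSpec",
    "Network",
    "NetworkResult",
    "NetworkStats",
    "build_network",
    "simulate_network",
    "compute_stats",
    "stimulus_response_profile",
    "is_asynchronous_irregular",
]

#: refuse to build networks with more expected edges than this
DEFAULT_EDGE_BUDGET = 5_000_000


@dataclass(frozen=True)
class HomeostasisEntry:
    """Compensation applied at a given health level: excitatory weights are
    scaled and the spike threshold / reset are shifted (mV)."""

    alpha: float
    wE_scale: float = 1.0
    Vth_shift: float = 0.0
    Vr_shift: float = 0.0


@dataclass(frozen=True)
class StimulusSpec:
    """Rate multiplier applied to the Poisson drive of a target subset
    (the first ``subset_size`` excitatory neurons) inside a time window."""

    subset_size: int = 100
    rate_multiplier: float = 3.0
    window: tuple[float, float] = (1400.0, 1650.0)


@dataclass(frozen=True)
class NetworkSpec:
    """Topology, drive and homeostasis schedule of an E/I network."""

    N: int = 1000
    exc_fraction: float = 0.8
    density: float = 0.1
    wE: float = 20.0  # pA, excitatory synaptic weight
    wI: float = 100.0  # pA, inhibitory synaptic weight (magnitude)
    delay: float = 1.5  # ms
    tau_syn: float = 2.0  # ms
    bg_rate: float = 4000.0  # Hz per neuron, Poisson background
    bg_weight: Optional[float] = None  # defaults to wE
    stimulus: Optional[StimulusSpec] = None
    homeostasis: tuple[HomeostasisEntry, ...] = (HomeostasisEntry(alpha=1.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.exc_fraction < 1.0):
            raise ValueError("exc_fraction must lie in (0, 1)")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.bg_rate < 0:
            raise ValueError("bg_rate must be non-negative")

    @property
    def n_exc(self) -> int:
        """Number of excitatory neurons (floor of N * exc_fraction)."""
        return int(self.N * self.exc_fraction)

    def entry_for(self, alpha: float) -> HomeostasisEntry:
        """The homeostasis entry whose alpha is closest to the requested one."""
        return min(self.homeostasis, key=lambda e: abs(e.alpha - alpha))


@dataclass
class Network:
    """A realized network: adjacency as per-source target arrays."""

    spec: NetworkSpec
    targets: list[np.ndarray]  # targets[j] = postsynaptic ids of source j
    is_exc: np.ndarray  # bool per neuron

    @property
    def N(self) -> int:
        return self.spec.N

    @property
    def n_edges(self) -> int:
        return int(sum(len(t) for t in self.targets))


@dataclass
class NetworkResult:
    """Spike trains (one sorted array of times per neuron) plus bookkeeping."""

    spike_trains: list[np.ndarray]
    duration: float
    dt: float
    alpha: float
    params: Params
    spec: NetworkSpec
    sampled_t: Optional[np.ndarray] = None
    sampled_V: Optional[np.ndarray] = None  # (n_sampled, n_times)
    sampled_eps: Optional[np.ndarray] = None
    sampled_ids: Optional[np.ndarray] = None
    death_times: Optional[np.ndarray] = None  # NaN where alive


@dataclass
class NetworkStats:
    """Per-neuron and pairwise summary statistics over a stated window."""

    rates: np.ndarray  # Hz per neuron
    cvs: np.ndarray  # ISI CV per neuron; NaN where < 5 spikes
    mean_cc: float  # mean pairwise Pearson correlation of binned counts
    window: tuple[float, float]
    bin_size: float

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates))

    @property
    def median_rate(self) -> float:
        return float(np.median(self.rates))

    @property
    def mean_cv(self) -> float:
        valid = self.cvs[np.isfinite(self.cvs)]
        return float(np.mean(valid)) if len(valid) else float("nan")


def build_network(
    spec: NetworkSpec, edge_budget: int = DEFAULT_EDGE_BUDGET
) -> Network:
    """Directed Erdos-Renyi network: every ordered pair (no self-loops) is an
    edge independently with probability ``density``.  Reproducible from
    ``spec.seed``."""
    expected = spec.density * spec.N * (spec.N - 1)
    if expected > edge_budget:
        raise ConfigError(
            f"network too large: ~{expected:.0f} expected edges exceed the "
            f"budget of {edge_budget}"
        )
    rng = np.random.default_rng(spec.seed)
    is_exc = np.zeros(spec.N, dtype=bool)
    is_exc[: spec.n_exc] = True
    targets: list[np.ndarray] = []
    for j in range(spec.N):
        if spec.density == 0.0:
            targets.append(np.empty(0, dtype=np.int64))
            continue
        mask = rng.random(spec.N) < spec.density
        mask[j] = False
        targets.append(np.flatnonzero(mask))
    return Network(spec=spec, targets=targets, is_exc=is_exc)


def _apply_homeostasis(
    p: Params, spec: NetworkSpec, alpha: float
) -> tuple[Params, float]:
    entry = spec.entry_for(alpha)
    p2 = replace(
        p,
        alpha=alpha,
        Vth=p.Vth + entry.Vth_shift,
        Vr=p.Vr + entry.Vr_shift,
    )
    return p2, entry.wE_scale


def simulate_network(
    net: Network,
    neuron_params: Params,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    alpha: Optional[float] = None,
    record_ids: Sequence[int] = (),
    record_every: int = 10,
) -> NetworkResult:
    """Simulate the network for ``duration`` ms.

    All neurons share one parameter set, adjusted by the homeostasis entry
    for ``alpha`` (default: the parameter set's own alpha).  Poisson
    generators are independent per neuron; the stimulus window multiplies the
    background rate of the target subset.  Deterministic given
    ``(net, neuron_params, duration, dt, seed, alpha)``.
    """
    spec = net.spec
    if alpha is None:
        alpha = neuron_params.alpha
    p, wE_scale = _apply_homeostasis(neuron_params, spec, alpha)
    madexp = isinstance(p, MAdExpParams)

    N = spec.N
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)

    delay_steps = max(1, int(round(spec.delay / dt)))
    ring = np.zeros((delay_steps, N))
    syn_decay = math.exp(-dt / spec.tau_syn)
    wE = spec.wE * wE_scale
    wI = spec.wI
    weight_of = np.where(net.is_exc, wE, -wI)

    bg_w = spec.bg_weight if spec.bg_weight is not None else wE
    lam = spec.bg_rate * dt * 1e-3
    stim = spec.stimulus
    if stim is not None:
        stim_ids = np.arange(min(stim.subset_size, spec.n_exc))
        w0, w1 = stim.window

    # state
    e_init = p.alpha * p.eps0
    V = np.full(N, effective_leak(e_init, p))
    eps = np.full(N, e_init)
    w = np.zeros(N)
    alive = np.ones(N, dtype=bool)
    death_times = np.full(N, np.nan)
    I_syn = np.zeros(N)

    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    rec = [i for i in record_ids if 0 <= i < N]
    if rec:
        n_rec = n_steps // record_every + 1
        sampled_t = np.empty(n_rec)
        sampled_V = np.empty((len(rec), n_rec))
        sampled_eps = np.empty((len(rec), n_rec))
        sampled_t[0] = 0.0
        sampled_V[:, 0] = V[rec]
        sampled_eps[:, 0] = eps[rec]
        rec_i = 1

    Cm, gL, E0, Eu, Ef, Ed = p.Cm, p.gL, p.E0, p.Eu, p.Ef, p.Ed
    Vth, Vr, eps0, epsc = p.Vth, p.Vr, p.eps0, p.epsc
    tau_e, delta, aeps0 = p.tau_e, p.delta, p.alpha * p.eps0
    dEdF = Ed - Ef
    Ie = p.Ie_baseline
    if madexp:
        DeltaT, Vpeak, a_ad, b_ad = p.DeltaT, p.Vpeak, p.a, p.b
        tau_w, gamma, IKATP = p.tau_w, p.gamma, p.I_KATP

    def deriv(V, eps, w, Itot):
        EL = E0 + (Eu - E0) * (1.0 - eps / eps0)
        if madexp:
            # cap the voltage seen by the exponential and the coupled
            # equations at the cutoff so a steep upswing cannot corrupt
            # eps and w before the reset is applied
            Vx = np.minimum(V, Vpeak)
            ex = np.minimum((Vx - Vth) / DeltaT, 20.0)
            dV = (
                gL * (EL - V)
                + gL * DeltaT * ((eps - epsc) / eps0) * np.exp(ex)
                - w
                + Itot
            ) / Cm
            de = (
                (1.0 - eps / aeps0) ** 3 - (Vx - Ef) / dEdF - w / gamma
            ) / tau_e
            denom = epsc + 2.0 * np.maximum(eps, 0.0)
            katp = np.divide(
                epsc, denom, out=np.zeros_like(denom), where=denom > 0
            ) * IKATP
            dw = (a_ad * (Vx - EL) - w + katp) / tau_w
            return dV, de, dw
        dV = (gL * (EL - V) + Itot) / Cm
        de = ((1.0 - eps / aeps0) ** 3 - (V - Ef) / dEdF) / tau_e
        return dV, de, 0.0

    h = dt
    for n in range(n_steps):
        t_next = (n + 1) * dt
        slot = n % delay_steps

        # Poisson background (independent per neuron; stimulus multiplies the
        # rate of the target subset inside the window)
        if lam > 0:
            counts = rng.poisson(lam, N)
            if stim is not None and w0 <= n * dt < w1:
                extra = rng.poisson(lam * (stim.rate_multiplier - 1.0), len(stim_ids))
                counts[stim_ids] += extra
            I_syn += counts * bg_w
        # delayed recurrent arrivals
        I_syn += ring[slot]
        ring[slot] = 0.0

        Itot = I_syn + Ie
        Vp, ep, wp = V.copy(), eps.copy(), w.copy()
        k1 = deriv(V, eps, w, Itot)
        k2 = deriv(
            V + 0.5 * h * k1[0], eps + 0.5 * h * k1[1], w + 0.5 * h * k1[2], Itot
        )
        k3 = deriv(
            V + 0.5 * h * k2[0], eps + 0.5 * h * k2[1], w + 0.5 * h * k2[2], Itot
        )
        k4 = deriv(V + h * k3[0], eps + h * k3[1], w + h * k3[2], Itot)
        V = V + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        eps = eps + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if madexp:
            w = w + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        # frozen dead neurons
        if not alive.all():
            dead = ~alive
            V[dead] = Vp[dead]
            eps[dead] = ep[dead]
            w[dead] = wp[dead]

        I_syn *= syn_decay

        if madexp:
            spk = (V >= Vpeak) & alive
        else:
            spk = (V >= Vth) & (eps >= epsc) & alive
        if spk.any():
            ids = np.flatnonzero(spk)
            V[ids] = Vr
            eps[ids] -= delta
            if madexp:
                w[ids] += b_ad
            spike_steps.append(np.full(len(ids), n + 1, dtype=np.int64))
            spike_ids.append(ids)
            # delayed delivery
            dslot = (n + delay_steps) % delay_steps  # == slot; arrival n+delay
            for j in ids:
                tg = net.targets[j]
                if len(tg):
                    ring[dslot, tg] += weight_of[j]

        newly_dead = alive & (eps <= 0.0) & (V >= Ed)
        if newly_dead.any():
            alive[newly_dead] = False
            death_times[newly_dead] = t_next

        if rec and (n + 1) % record_every == 0:
            sampled_t[rec_i] = t_next
            sampled_V[:, rec_i] = V[rec]
            sampled_eps[:, rec_i] = eps[rec]
            rec_i += 1

    if spike_steps:
        all_steps = np.concatenate(spike_steps)
        all_ids = np.concatenate(spike_ids)
    else:
        all_steps = np.empty(0, dtype=np.int64)
        all_ids = np.empty(0, dtype=np.int64)
    trains = [
        np.sort(all_steps[all_ids == i]) * dt for i in range(N)
    ]

    return NetworkResult(
        spike_trains=trains,
        duration=duration,
        dt=dt,
        alpha=alpha,
        params=p,
        spec=spec,
        sampled_t=sampled_t[:rec_i] if rec else None,
        sampled_V=sampled_V[:, :rec_i] if rec else None,
        sampled_eps=sampled_eps[:, :rec_i] if rec else None,
        sampled_ids=np.asarray(rec) if rec else None,
        death_times=death_times,
    )


def compute_stats(
    spike_trains: Sequence[np.ndarray],
    window: tuple[float, float],
    bin_size: float = 5.0,
    n_pairs: int = 2000,
    seed: int = 0,
) -> NetworkStats:
    """Rates, ISI CVs and mean pairwise cross-correlation over a window.

    Rates are spike counts divided by the window length.  CVs are computed
    for neurons with at least 5 spikes in the window (NaN otherwise).  The
    cross-correlation is the mean Pearson correlation of spike counts binned
    at ``bin_size`` ms over a seeded random subsample of neuron pairs; pairs
    containing a constant (e.g. silent) train are skipped.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    N = len(spike_trains)
    dur_s = (t1 - t0) * 1e-3

    rates = np.empty(N)
    cvs = np.full(N, np.nan)
    edges = np.arange(t0, t1 + bin_size * 0.5, bin_size)
    counts = np.zeros((N, len(edges) - 1))
    for i, tr in enumerate(spike_trains):
        tr = np.asarray(tr)
        sel = tr[(tr >= t0) & (tr < t1)]
        rates[i] = len(sel) / dur_s
        if len(sel) >= 5:
            isi = np.diff(sel)
            m = isi.mean()
            cvs[i] = isi.std() / m if m > 0 else np.nan
        counts[i], _ = np.histogram(sel, edges)

    rng = np.random.default_rng(seed)
    ccs = []
    max_pairs = N * (N - 1) // 2
    n_pairs = min(n_pairs, max_pairs)
    seen = set()
    attempts = 0
    while len(seen) < n_pairs and attempts < 50 * n_pairs:
        i, j = rng.integers(0, N, 2)
        attempts += 1
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        a, b = counts[key[0]], counts[key[1]]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        ccs.append(float(np.corrcoef(a, b)[0, 1]))
    mean_cc = float(np.mean(ccs)) if ccs else float("nan")
    return NetworkStats(
        rates=rates, cvs=cvs, mean_cc=mean_cc, window=(t0, t1), bin_size=bin_size
    )


def is_asynchronous_irregular(
    stats: NetworkStats, N: int, cv_range: tuple[float, float] = (0.5, 1.2)
) -> bool:
    """Asynchronous-irregular label: mean pairwise CC below 1/N and mean ISI
    CV within ``cv_range``."""
    return (
        stats.mean_cc < 1.0 / N
        and cv_range[0] <= stats.mean_cv <= cv_range[1]
    )


def stimulus_response_profile(
    spike_trains: Sequence[np.ndarray],
    subset: Sequence[int],
    window: tuple[float, float],
    background_window: Optional[tuple[float, float]] = None,
    bin_size: float = 5.0,
    k: float = 3.0,
    min_gap: float = 20.0,
) -> dict:
    """Burst/tonic transition metrics for a target subset during a window.

    The population rate of the subset is binned at ``bin_size`` ms; bins above
    ``k`` times the subset's background rate are "active".  Contiguous active
    stretches separated by more than ``min_gap`` ms count as distinct bursts.
    Returns burst count, fraction of window time active, and the mean
    intra-burst population rate (Hz per neuron).
    """
    subset = np.asarray(subset)
    t0, t1 = window
    pooled = np.concatenate(
        [np.asarray(spike_trains[i]) for i in subset]
    ) if len(subset) else np.empty(0)
    sel = pooled[(pooled >= t0) & (pooled < t1)]
    edges = np.arange(t0, t1 + bin_size * 0.5, bin_size)
    counts, _ = np.histogram(sel, edges)
    rate = counts / (len(subset) * bin_size * 1e-3)  # Hz per neuron

    if background_window is not None:
        b0, b1 = background_window
        bg_n = np.sum((pooled >= b0) & (pooled < b1))
        bg_rate = bg_n / (len(subset) * (b1 - b0) * 1e-3)
    else:
        bg_rate = float(np.median(rate))
    thresh = k * max(bg_rate, 1e-9)

    active = rate > thresh
    # merge active bins into bursts, allowing gaps up to min_gap
    gap_bins = max(1, int(round(min_gap / bin_size)))
    bursts: list[tuple[int, int]] = []
    i = 0
    nb = len(active)
    while i < nb:
        if active[i]:
            j = i
            last_active = i
            while j + 1 < nb and (active[j + 1] or (j + 1 - last_active) <= gap_bins):
                j += 1
                if active[j]:
                    last_active = j
            bursts.append((i, last_active))
            i = last_active + 1
        else:
            i += 1
    frac_active = float(np.mean(active))
    intra = (
        float(np.mean([rate[a : b + 1].mean() for a, b in bursts]))
        if bursts
        else 0.0
    )
    return {
        "burst_count": len(bursts),
        "fraction_active": frac_active,
        "mean_intra_burst_rate": intra,
        "background_rate": float(bg_rate),
        "bin_rate": rate,
    }
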