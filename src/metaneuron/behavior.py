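"""Spiking-behavior classification.

Maps a simulated response to a single-step protocol onto a small repertoire
of qualitative labels (regular spiking, adapting, bursting variants, delayed
onsets, transient spiking, rebounds, intermittent spiking, depolarization
block, silent) through an explicit feature set and deterministic threshold
rules.  All thresholds live in :class:`ClassifierThresholds` and are plain
package defaults — the labels are qualitative by nature.

The expected protocol contains exactly one principal step (the segment with
the largest absolute amplitude); depolarizing steps probe the spiking
repertoire, hyperpolarizing steps probe sag and post-inhibitory rebound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .models import MAdExpParams, Params
from .phase import rebound_threshold
from .simulate import Protocol, SimulationResult, detect_depolarization_block

__all__ = [
    "ClassifierThresholds",
    "Features",
    "BehaviorReport",
    "extract_features",
    "classify",
    "classify_response",
    "rebound_mode",
    "LABELS",
]

LABELS = (
    "RS",  # regular spiking
    "AS",  # adapting spiking
    "IB",  # initial burst, then regular
    "RB",  # regular bursting
    "TS",  # transient spiking (stops while energy recovers)
    "DB",  # delayed bursting
    "DA",  # delayed accelerating
    "IR",  # post-inhibitory rebound
    "ER",  # post-excitatory rebound
    "IS",  # intermittent spiking
    "depol-block",
    "silent",
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the rule-based classifier (package defaults)."""

    adaptation: float = 0.1  # |adaptation index| boundary for RS vs AS
    latency_fraction: float = 0.3  # of step duration: "delayed" onset
    burstiness: float = 0.5  # intra/inter ISI median ratio below -> bursty
    sag: float = 0.05  # sag ratio above -> sag present
    rebound_window: float = 300.0  # ms after step offset
    block_min_duration: float = 50.0  # ms of superthreshold silence
    gap_cv_regular: float = 0.5  # CV of inter-burst gaps below -> regular
    early_stop_fraction: float = 0.8  # last spike before this fraction -> stopped


@dataclass
class Features:
    """Quantitative features of one response to a single-step protocol."""

    step_onset: float
    step_offset: float
    step_amplitude: float
    n_spikes: int  # total over the whole simulation
    n_spikes_step: int  # spikes inside [onset, offset)
    latency: Optional[float]  # first step spike - onset (ms)
    isis: np.ndarray  # ISIs of the step spikes (ms)
    adaptation_index: Optional[float]
    burstiness: Optional[float]
    n_bursts: Optional[int]
    gap_cv: Optional[float]  # CV of inter-burst intervals (>= 3 bursts)
    initial_burst_only: bool  # all short ISIs precede all long ISIs
    monotone_fraction: Optional[float]  # fraction of lengthening ISI steps
    accelerating: bool  # monotonic trend toward shorter ISIs
    sag_ratio: Optional[float]  # hyperpolarizing steps only
    rebound_count: int  # spikes in (offset, offset + window]
    stopped_early: bool  # last step spike well before the offset
    block_intervals: list  # superthreshold-silent intervals during the step
    V_final: float
    eps_final: float
    eps_recovering: bool  # energy rising at the end of the step
    died: bool


@dataclass
class BehaviorReport:
    """Primary label plus the features and any runner-up labels."""

    label: str
    features: Features
    secondary: list = field(default_factory=list)


def _principal_step(proto: Protocol) -> tuple[float, float, float]:
    if not proto.segments:
        raise ConfigError(
            "behavior classification requires a protocol with one principal step"
        )
    return max(proto.segments, key=lambda s: abs(s[2]))


def _two_means_log_isi(isis: np.ndarray) -> tuple[float, np.ndarray]:
    """2-means split of log-ISIs.

    Returns ``(burstiness, short_mask)`` where burstiness is the ratio of the
    short-class median to the long-class median (1 for a unimodal train) and
    ``short_mask`` flags the intra-burst (short) ISIs.
    """
    x = np.log(isis)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return 1.0, np.zeros(len(isis), dtype=bool)
    c = np.array([lo, hi])
    for _ in range(100):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array(
            [x[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    short = assign == 0
    if not short.any() or short.all():
        return 1.0, np.zeros(len(isis), dtype=bool)
    ratio = float(np.median(isis[short]) / np.median(isis[~short]))
    return ratio, short


def extract_features(
    result: SimulationResult,
    proto: Protocol,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> Features:
    """Compute the feature set of a response to a single-step protocol.

    With fewer than 2 spikes during the step the ISI-based features are
    reported as not-applicable (``None``).
    """
    onset, offset, amp = _principal_step(proto)
    th = thresholds
    spikes = np.asarray(result.spike_times, dtype=float)
    in_step = spikes[(spikes >= onset) & (spikes < offset)]
    latency = float(in_step[0] - onset) if len(in_step) else None
    isis = np.diff(in_step)

    adaptation = burstiness = gap_cv = None
    n_bursts: Optional[int] = None
    initial_burst_only = False
    monotone_fraction = None
    accelerating = False
    if len(isis) >= 1:
        first, last = float(isis[0]), float(isis[-1])
        if first + last > 0 and len(isis) >= 2:
            adaptation = (last - first) / (last + first)
        burstiness, short = _two_means_log_isi(isis)
        if short.any() and not short.all():
            # bursts = maximal runs not separated by a long (inter-burst) ISI
            n_bursts = int(np.sum(~short)) + 1
            long_isis = isis[~short]
            if len(long_isis) >= 2:
                gap_cv = float(np.std(long_isis) / np.mean(long_isis))
            short_idx = np.flatnonzero(short)
            long_idx = np.flatnonzero(~short)
            initial_burst_only = (
                len(short_idx) > 0
                and len(long_idx) > 0
                and short_idx.max() < long_idx.min()
            )
        if len(isis) >= 2:
            steps = np.diff(isis)
            monotone_fraction = float(np.mean(steps > 0))
        if len(isis) >= 3:
            # robust monotone-trend check on the ISI sequence
            slope = np.polyfit(np.arange(len(isis)), isis, 1)[0]
            accelerating = slope < 0 and isis[-1] < 0.8 * isis[0]

    sag_ratio = None
    if amp < 0:
        t = result.t
        i_on = int(np.searchsorted(t, onset))
        i_off = int(np.searchsorted(t, offset))
        if i_off - i_on > 4:
            seg = result.V[i_on:i_off]
            v_base = float(result.V[max(i_on - 1, 0)])
            n_tail = max(1, (i_off - i_on) // 20)
            v_steady = float(np.mean(seg[-n_tail:]))
            v_min = float(seg.min())
            denom = v_min - v_base
            sag_ratio = (v_min - v_steady) / denom if abs(denom) > 1e-9 else 0.0

    rebound_count = int(
        np.sum((spikes > offset) & (spikes <= offset + th.rebound_window))
    )

    stopped_early = bool(
        len(in_step)
        and in_step[-1] < onset + th.early_stop_fraction * (offset - onset)
    )

    blocks = [
        (a, b)
        for a, b in detect_depolarization_block(
            result, result.params, min_duration=th.block_min_duration
        )
        if a < offset and b > onset
    ]

    i_end = int(np.searchsorted(result.t, offset)) - 1
    i_end = max(0, min(i_end, len(result.t) - 1))
    # energy recovery after the (last) in-step spike: the post-stop energy
    # minimum is followed by a rise before the step ends
    t_last = in_step[-1] if len(in_step) else onset
    i_from = int(np.searchsorted(result.t, t_last))
    i_from = min(i_from, i_end)
    tail = result.eps[i_from : i_end + 1]
    eps_recovering = bool(
        len(tail) > 2 and tail[-1] > float(tail.min()) + 1e-9
    )

    return Features(
        step_onset=onset,
        step_offset=offset,
        step_amplitude=amp,
        n_spikes=len(spikes),
        n_spikes_step=len(in_step),
        latency=latency,
        isis=isis,
        adaptation_index=adaptation,
        burstiness=burstiness,
        n_bursts=n_bursts,
        gap_cv=gap_cv,
        initial_burst_only=initial_burst_only,
        monotone_fraction=monotone_fraction,
        accelerating=accelerating,
        sag_ratio=sag_ratio,
        rebound_count=rebound_count,
        stopped_early=stopped_early,
        block_intervals=blocks,
        V_final=float(result.V[i_end]),
        eps_final=float(result.eps[i_end]),
        eps_recovering=eps_recovering,
        died=result.death_time is not None,
    )


def classify(
    f: Features, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> BehaviorReport:
    """Deterministic rule-based label from a feature set.

    Priority order: depolarization block, rebound labels (IR/ER), delayed
    labels (DB/DA), burst labels (IB/RB/IS), TS, AS, RS, silent.  Runner-up
    rules that also fired are listed as secondary candidates.
    """
    th = thresholds
    candidates: list[str] = []

    def hit(label: str, cond: bool) -> bool:
        if cond:
            candidates.append(label)
        return cond

    # a smoothly lengthening ISI sequence is adaptation, not bursting, even
    # though a 2-means split of its ISIs looks mildly bimodal; an
    # order-of-magnitude gap between the ISI classes is a true burst
    smooth_adapting = (
        f.monotone_fraction is not None
        and f.monotone_fraction >= 0.75
        and f.burstiness is not None
        and f.burstiness > 0.1
    )
    bursty = (
        f.burstiness is not None
        and f.burstiness < th.burstiness
        and not smooth_adapting
    )
    delayed = (
        f.latency is not None
        and f.latency > th.latency_fraction * (f.step_offset - f.step_onset)
    )
    regular_gaps = f.gap_cv is None or f.gap_cv < th.gap_cv_regular

    hit("depol-block", bool(f.block_intervals))
    hit(
        "IR",
        f.step_amplitude < 0 and f.n_spikes_step == 0 and f.rebound_count > 0,
    )
    hit(
        "ER",
        f.step_amplitude > 0 and f.n_spikes_step == 0 and f.rebound_count > 0,
    )
    hit("DB", delayed and bursty)
    hit("DA", delayed and f.accelerating)
    hit("IB", bursty and f.initial_burst_only and not f.stopped_early)
    hit(
        "RB",
        bursty
        and not f.initial_burst_only
        and (f.n_bursts or 0) >= 2
        and regular_gaps
        and not f.stopped_early,
    )
    hit(
        "IS",
        bursty
        and not f.initial_burst_only
        and (f.n_bursts or 0) >= 2
        and not regular_gaps,
    )
    hit(
        "TS",
        f.n_spikes_step > 0
        and f.stopped_early
        and not f.block_intervals
        and f.eps_recovering,
    )
    hit(
        "AS",
        f.n_spikes_step >= 3
        and not f.stopped_early
        and f.adaptation_index is not None
        and f.adaptation_index > th.adaptation,
    )
    hit(
        "RS",
        f.n_spikes_step >= 3
        and not f.stopped_early
        and not bursty
        and f.adaptation_index is not None
        and abs(f.adaptation_index) <= th.adaptation,
    )
    hit("silent", f.n_spikes == 0)

    if not candidates:
        # spikes occurred but no specific pattern fired; fall back on the
        # closest generic label
        if f.n_spikes_step == 0:
            candidates.append("silent")
        elif f.adaptation_index is not None and f.adaptation_index > th.adaptation:
            candidates.append("AS")
        else:
            candidates.append("RS")
    return BehaviorReport(
        label=candidates[0], features=f, secondary=candidates[1:]
    )


def classify_response(
    result: SimulationResult,
    proto: Protocol,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> BehaviorReport:
    """Convenience wrapper: extract features, then classify."""
    return classify(extract_features(result, proto, thresholds), thresholds)


def rebound_mode(
    p: Params,
    result: SimulationResult,
    proto: Protocol,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> str:
    """Discriminate the two rebound mechanisms on a hyperpolarizing protocol.

    Returns ``"sag-rebound"`` (adaptation-current mechanism, sag present),
    ``"no-sag-rebound"`` (energy-mediated mechanism, no sag) or ``"none"``.
    A no-sag rebound is only reported when a mechanism that can produce it is
    actually present: either the energy-mediated rebound condition applies
    (``rebound_threshold``) or subthreshold adaptation exists.
    """
    f = extract_features(result, proto, thresholds)
    if f.rebound_count == 0:
        return "none"
    sag = (f.sag_ratio or 0.0) > thresholds.sag
    if sag:
        return "sag-rebound"
    has_energy_mechanism = False
    if isinstance(p, MAdExpParams):
        rb = rebound_threshold(p)
        has_energy_mechanism = rb is not None and rb[1]
    else:
        has_energy_mechanism = p.Eu != p.E0
    has_adaptation = isinstance(p, MAdExpParams) and (p.a != 0 or p.b != 0)
    if has_energy_mechanism or has_adaptation:
        return "no-sag-rebound"
    return "none"
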