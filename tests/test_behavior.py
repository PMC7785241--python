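"""Behavior classification: preset self-consistency and classifier rules."""

import numpy as np
import pytest

from metaneuron import (
    Protocol,
    integrate,
    preset_params,
    preset_protocol,
)
from metaneuron.behavior import (
    Features,
    classify,
    classify_response,
    extract_features,
    rebound_mode,
)
from metaneuron.errors import ConfigError
from metaneuron.simulate import SimulationResult

from conftest import BEHAVIOR_PRESETS


# ------------------------------------------------- preset self-consistency

@pytest.mark.parametrize("name", sorted(BEHAVIOR_PRESETS))
def test_preset_classifies_as_its_own_label(name, fig6_classify):
    label, key = BEHAVIOR_PRESETS[name]
    report, _, _ = fig6_classify(name, key)
    assert report.label == label


@pytest.mark.parametrize("name", sorted(BEHAVIOR_PRESETS))
def test_strong_step_gives_depolarization_block(name, fig6_classify):
    report, _, _ = fig6_classify(name, "red")
    assert report.label == "depol-block"


def test_trailing_silence_does_not_change_label():
    p = preset_params("fig6_RS")
    proto = preset_protocol("fig6_RS", "yellow")
    longer = Protocol(duration=proto.duration + 500.0, segments=proto.segments)
    res = integrate(p, None, longer, dt=0.05, seed=0)
    assert classify_response(res, longer).label == "RS"


def test_rebound_modes_on_presets():
    # post-inhibitory rebound rides on a visible sag; post-excitatory rebound
    # is the energy-mediated mechanism with no sag
    cases = {
        ("fig6_IR", "blue"): "sag-rebound",
        ("fig6_ER", "yellow"): "no-sag-rebound",
        ("fig6_RS", "yellow"): "none",
    }
    for (name, key), expected in cases.items():
        p = preset_params(name)
        proto = preset_protocol(name, key)
        res = integrate(p, None, proto, dt=0.05, seed=0)
        assert rebound_mode(p, res, proto) == expected, name


# ----------------------------------------------------- classifier rule unit

def make_features(**kw):
    base = dict(
        step_onset=100.0,
        step_offset=1100.0,
        step_amplitude=200.0,
        n_spikes=0,
        n_spikes_step=0,
        latency=None,
        isis=np.array([]),
        adaptation_index=None,
        burstiness=None,
        n_bursts=None,
        gap_cv=None,
        initial_burst_only=False,
        monotone_fraction=None,
        accelerating=False,
        sag_ratio=None,
        rebound_count=0,
        stopped_early=False,
        block_intervals=[],
        V_final=-65.0,
        eps_final=1.0,
        eps_recovering=False,
        died=False,
    )
    base.update(kw)
    return Features(**base)


def spiking(**kw):
    base = dict(
        n_spikes=11,
        n_spikes_step=11,
        latency=20.0,
        isis=np.full(10, 90.0),
        adaptation_index=0.0,
        burstiness=1.0,
        monotone_fraction=0.5,
    )
    base.update(kw)
    return make_features(**base)


def test_rule_silent():
    assert classify(make_features()).label == "silent"


def test_rule_rebounds():
    ir = make_features(step_amplitude=-100.0, n_spikes=2, rebound_count=2)
    assert classify(ir).label == "IR"
    er = make_features(step_amplitude=200.0, n_spikes=1, rebound_count=1)
    assert classify(er).label == "ER"
    # spikes during the step disqualify the rebound labels
    not_er = spiking(rebound_count=1)
    assert classify(not_er).label == "RS"


def test_rule_rs_vs_as_boundary():
    assert classify(spiking(adaptation_index=0.05)).label == "RS"
    assert classify(spiking(adaptation_index=0.5)).label == "AS"
    # boundary value belongs to RS (|index| <= threshold)
    assert classify(spiking(adaptation_index=0.1)).label == "RS"


def test_rule_delayed_labels():
    db = spiking(latency=500.0, burstiness=0.2, n_bursts=3, gap_cv=0.3,
                 monotone_fraction=0.3)
    assert classify(db).label == "DB"
    da = spiking(latency=500.0, accelerating=True)
    assert classify(da).label == "DA"
    # short latency: the same bursty features are RB, not DB
    rb = spiking(latency=20.0, burstiness=0.2, n_bursts=3, gap_cv=0.3,
                 monotone_fraction=0.3)
    assert classify(rb).label == "RB"


def test_rule_burst_family():
    ib = spiking(burstiness=0.2, initial_burst_only=True, n_bursts=2,
                 monotone_fraction=0.3)
    assert classify(ib).label == "IB"
    is_ = spiking(burstiness=0.2, n_bursts=4, gap_cv=0.9,
                  monotone_fraction=0.3)
    assert classify(is_).label == "IS"


def test_rule_smooth_adaptation_is_not_bursting():
    # a smoothly lengthening ISI sequence can look mildly bimodal to a
    # 2-means split but must stay in the adapting family
    f = spiking(adaptation_index=0.4, burstiness=0.4, n_bursts=2,
                monotone_fraction=0.9)
    assert classify(f).label == "AS"


def test_rule_ts_and_block_priority():
    ts = spiking(stopped_early=True, eps_recovering=True)
    assert classify(ts).label == "TS"
    blocked = spiking(stopped_early=True, eps_recovering=True,
                      block_intervals=[(500.0, 700.0)])
    assert classify(blocked).label == "depol-block"


# -------------------------------------------- feature extraction on trains

def synth_result(spikes, duration=1500.0):
    """Flat subthreshold traces carrying a prescribed spike train."""
    dt = 1.0
    t = np.arange(int(duration / dt) + 1) * dt
    flat = np.full_like(t, -65.0)
    return SimulationResult(
        t=t,
        V=flat.copy(),
        eps=np.ones_like(t),
        w=np.zeros_like(t),
        spike_times=np.asarray(spikes, dtype=float),
        death_time=None,
        dt=dt,
        params=preset_params("fig6_RS"),
    )


PROTO = Protocol(duration=1500.0, segments=[(100.0, 1100.0, 200.0)])


def burst_train(starts, n=4, isi=8.0):
    return np.concatenate([s + isi * np.arange(n) for s in starts])


def test_burst_detection_regular_bursting():
    res = synth_result(burst_train([150.0, 450.0, 750.0, 1050.0]))
    f = extract_features(res, PROTO)
    assert f.n_bursts == 4
    assert f.burstiness < 0.5
    assert f.gap_cv == pytest.approx(0.0, abs=1e-9)
    assert not f.initial_burst_only
    assert classify(f).label == "RB"


def test_burst_detection_intermittent():
    res = synth_result(burst_train([150.0, 350.0, 900.0, 1050.0]))
    f = extract_features(res, PROTO)
    assert f.n_bursts == 4
    assert f.gap_cv > 0.5
    assert classify(f).label == "IS"


def test_initial_burst_then_tonic():
    spikes = np.concatenate(
        [150.0 + 8.0 * np.arange(5), np.arange(350.0, 1100.0, 90.0)]
    )
    res = synth_result(spikes)
    f = extract_features(res, PROTO)
    assert f.initial_burst_only
    assert classify(f).label == "IB"


def test_tonic_train_is_rs():
    res = synth_result(np.arange(150.0, 1100.0, 90.0))
    f = extract_features(res, PROTO)
    assert f.burstiness == pytest.approx(1.0)
    assert f.n_bursts is None
    assert classify(f).label == "RS"


def test_features_count_windows():
    res = synth_result([50.0, 200.0, 300.0, 1200.0])
    f = extract_features(res, PROTO)
    assert f.n_spikes == 4
    assert f.n_spikes_step == 2
    assert f.latency == pytest.approx(100.0)
    assert f.rebound_count == 1  # the 1200 ms spike, within 300 ms of offset


def test_protocol_without_step_is_rejected():
    res = synth_result([])
    with pytest.raises(ConfigError):
        extract_features(res, Protocol(duration=1500.0))
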