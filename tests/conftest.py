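"""Shared fixtures: generated file fixtures, cached expensive simulations."""

from __future__ import annotations

import dataclasses
import functools

import pytest

from metaneuron import (
    build_network,
    compute_stats,
    integrate,
    make_fixtures,
    preset_network,
    preset_params,
    preset_protocol,
    simulate_network,
)
from metaneuron.behavior import classify_response

#: the ten behavior presets and the key of their principal (non-block) protocol
BEHAVIOR_PRESETS = {
    "fig6_RS": ("RS", "yellow"),
    "fig6_AS": ("AS", "yellow"),
    "fig6_IB": ("IB", "yellow"),
    "fig6_RB": ("RB", "yellow"),
    "fig6_TS": ("TS", "yellow"),
    "fig6_DB": ("DB", "yellow"),
    "fig6_DA": ("DA", "yellow"),
    "fig6_IR": ("IR", "blue"),
    "fig6_ER": ("ER", "yellow"),
    "fig6_IS": ("IS", "yellow"),
}

AI_PRESET = "fig5_network_neuron"
AI_WARMUP = 500.0
AI_DURATION = 5500.0


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    make_fixtures(seed=0, out_dir=d)
    return d


@functools.lru_cache(maxsize=None)
def _classify_preset(name: str, key: str):
    p = preset_params(name)
    proto = preset_protocol(name, key)
    res = integrate(p, None, proto, dt=0.05, seed=0)
    return classify_response(res, proto), res, proto


@pytest.fixture(scope="session")
def fig6_classify():
    """Cached (report, result, protocol) per (preset, protocol key)."""
    return _classify_preset


@functools.lru_cache(maxsize=None)
def _ai_stats(alpha: float):
    """AI-network statistics at one health level (5 s window, 20k pairs).

    The preset's stimulus is disabled: the acceptance statistics describe
    the unstimulated background asynchronous-irregular state.
    """
    spec = dataclasses.replace(preset_network(AI_PRESET), stimulus=None)
    p = preset_params(AI_PRESET)
    net = build_network(spec)
    res = simulate_network(net, p, AI_DURATION, dt=0.1, seed=0, alpha=alpha)
    stats = compute_stats(
        res.spike_trains, (AI_WARMUP, AI_DURATION), n_pairs=20_000, seed=0
    )
    return stats, res


@pytest.fixture(scope="session")
def ai_stats():
    """Cached callable alpha -> (NetworkStats, NetworkResult)."""
    return _ai_stats
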