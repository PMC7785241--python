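"""Integrator tests: closed-form oracles, convergence, hybrid rules, death."""

import numpy as np
import pytest

from metaneuron import (
    ELIFParams,
    MAdExpParams,
    PoissonInput,
    Protocol,
    detect_depolarization_block,
    integrate,
    list_presets,
    preset_params,
    preset_protocol,
)


def lif_params(**kw):
    """eLIF in the LIF limit: Eu = E0, delta = 0, epsc = 0."""
    base = dict(
        Cm=200.0, gL=10.0, E0=-65.0, Eu=-65.0, Ef=-60.0, Ed=-45.0,
        Vth=-30.0, Vr=-60.0, eps0=1.0, epsc=0.0, tau_e=300.0, delta=0.0,
    )
    base.update(kw)
    return ELIFParams(**base)


def test_lif_closed_form_subthreshold():
    """V(t) = E0 + (I/gL)(1 - exp(-t/tau_m)) to <= 1e-6 mV at dt = 0.01."""
    p = lif_params()
    I = 100.0
    proto = Protocol(duration=200.0, segments=[(0.0, 200.0, I)])
    res = integrate(p, None, proto, dt=0.01)
    expected = p.E0 + (I / p.gL) * (1.0 - np.exp(-res.t / p.tau_m))
    assert res.n_spikes == 0
    assert np.max(np.abs(res.V - expected)) <= 1e-6


def test_lif_spiking_matches_analytic_period():
    # suprathreshold LIF: interspike interval tau_m ln((dv)/(dv - (Vth - Vr)))
    p = lif_params(Vth=-50.0, Vr=-60.0)
    I = 300.0  # dv = 30 mV from Vr toward -35
    proto = Protocol(duration=500.0, segments=[(0.0, 500.0, I)])
    res = integrate(p, None, proto, dt=0.005)
    dv = I / p.gL
    v_inf = p.E0 + dv
    period = p.tau_m * np.log((v_inf - p.Vr) / (v_inf - p.Vth))
    isis = res.isis()
    assert len(isis) > 5
    assert np.allclose(isis, period, atol=2 * 0.005)


def _reference_adexp(p, I, duration, dt, V0, w0):
    """Plain AdExp (no energy machinery), same RK4 stepping as integrate."""
    n = int(round(duration / dt))
    V, w = V0, w0
    out = np.empty(n + 1)
    out[0] = V

    def f(V, w):
        Vx = min(V, p.Vpeak)
        ex = min((Vx - p.Vth) / p.DeltaT, 20.0)
        dV = (p.gL * (p.E0 - V) + p.gL * p.DeltaT * np.exp(ex) - w + I) / p.Cm
        dw = (p.a * (Vx - p.E0) - w) / p.tau_w
        return dV, dw

    for i in range(n):
        k1 = f(V, w)
        k2 = f(V + 0.5 * dt * k1[0], w + 0.5 * dt * k1[1])
        k3 = f(V + 0.5 * dt * k2[0], w + 0.5 * dt * k2[1])
        k4 = f(V + dt * k3[0], w + dt * k3[1])
        V += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        w += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        out[i + 1] = V
    return out


def test_adexp_reduction_matches_reference():
    """mAdExp with eps pinned at eps0 + epsc, Eu = E0, gamma -> inf equals a
    direct AdExp implementation to <= 1e-6 mV subthreshold."""
    p = MAdExpParams(
        Cm=200.0, gL=10.0, E0=-65.0, Eu=-65.0, Ef=-60.0, Ed=-45.0,
        Vth=-50.0, Vr=-58.0, eps0=1.0, epsc=0.1, tau_e=1e9, delta=0.0,
        DeltaT=2.0, Vpeak=0.0, a=4.0, b=0.0, tau_w=100.0, gamma=1e15,
        I_KATP=0.0,
    )
    from metaneuron.models import NeuronState

    I, duration, dt = 60.0, 500.0, 0.01  # subthreshold drive
    s0 = NeuronState(V=p.E0, eps=p.eps0 + p.epsc, w=0.0)
    proto = Protocol(duration=duration, segments=[(0.0, duration, I)])
    res = integrate(p, s0, proto, dt=dt)
    ref = _reference_adexp(p, I, duration, dt, p.E0, 0.0)
    assert res.n_spikes == 0
    assert np.max(np.abs(res.V - ref)) <= 1e-6


def _strip_poisson(proto):
    return Protocol(duration=proto.duration, segments=proto.segments,
                    poisson=None, alpha_schedule=proto.alpha_schedule)


@pytest.mark.parametrize("name", sorted(list_presets()))
def test_dt_halving_convergence(name):
    """Spike times shift by <= 2*dt when dt is halved, for every preset.

    Poisson noise is removed: its realization is dt-dependent by
    construction, so convergence is a statement about the deterministic flow.
    """
    p = preset_params(name)
    proto = _strip_poisson(preset_protocol(name))
    dt = 0.05
    a = integrate(p, None, proto, dt=dt)
    b = integrate(p, None, proto, dt=dt / 2.0)
    assert a.n_spikes == b.n_spikes
    if a.n_spikes:
        assert np.max(np.abs(a.spike_times - b.spike_times)) <= 2 * dt


def test_energy_cost_per_spike():
    p = preset_params("fig6_RS")
    proto = preset_protocol("fig6_RS", "yellow")
    res = integrate(p, None, proto, dt=0.05)
    assert res.n_spikes >= 3
    # eps drops by delta across each spike step (minus one step of smooth flow)
    for ts in res.spike_times[:5]:
        i = int(np.floor(ts / res.dt)) + 1  # record index at the step end
        jump = res.eps[i] - res.eps[i - 1]
        assert jump == pytest.approx(-p.delta, abs=0.2 * p.delta)


def test_no_spikes_below_critical_energy():
    # start with sustainable energy below epsc: superthreshold drive produces
    # a depolarization block, never a spike
    p = ELIFParams(alpha=0.2, epsc=0.5, Vth=-50.0, Vr=-60.0, Ed=-20.0)
    proto = Protocol(duration=1000.0, segments=[(100.0, 900.0, 400.0)])
    res = integrate(p, None, proto)
    assert res.n_spikes == 0
    assert np.max(res.V) > p.Vth
    blocks = detect_depolarization_block(res)
    assert blocks and blocks[0][1] - blocks[0][0] >= 50.0


def test_death_freezes_state():
    p = ELIFParams(
        E0=-65.0, Eu=-65.0, Ef=-60.0, Ed=-40.0, Vth=-50.0, Vr=-58.0,
        epsc=0.3, delta=0.2, tau_e=1000.0,
    )
    proto = Protocol(duration=3000.0, segments=[(100.0, 3000.0, 500.0)])
    res = integrate(p, None, proto)
    assert res.death_time is not None
    assert not res.alive
    # no spikes after death, trace frozen from the death step on
    assert not np.any(res.spike_times > res.death_time)
    i = int(round(res.death_time / res.dt))
    assert np.all(res.V[i:] == res.V[i])
    assert np.all(res.eps[i:] == res.eps[i])
    # frozen at a superthreshold depolarized potential with no energy
    assert res.V[i] >= p.Ed and res.eps[i] <= 0.0


def test_poisson_determinism_and_seed_dependence():
    p = ELIFParams()
    proto = Protocol(duration=500.0,
                     poisson=PoissonInput(rate=500.0, weight=50.0))
    a = integrate(p, None, proto, seed=7)
    b = integrate(p, None, proto, seed=7)
    c = integrate(p, None, proto, seed=8)
    assert np.array_equal(a.V, b.V)
    assert not np.array_equal(a.V, c.V)


def test_poisson_delta_kind_jumps_voltage():
    p = ELIFParams()
    proto = Protocol(
        duration=200.0,
        poisson=PoissonInput(rate=200.0, weight=400.0, kind="delta"),
    )
    res = integrate(p, None, proto, seed=3)
    assert np.max(res.V) > p.E0 + 0.5  # events arrived and depolarized


def test_refractory_clamps_isis():
    p = lif_params(Vth=-50.0, Vr=-60.0)
    proto = Protocol(duration=500.0, segments=[(0.0, 500.0, 400.0)])
    free = integrate(p, None, proto)
    ref = integrate(p, None, proto, refractory=10.0)
    assert np.min(free.isis()) < 10.0
    assert np.min(ref.isis()) >= 10.0


def test_record_every_subsamples():
    p = ELIFParams()
    proto = Protocol(duration=100.0)
    res = integrate(p, None, proto, dt=0.05, record_every=20)
    assert res.t[1] - res.t[0] == pytest.approx(1.0)
    assert len(res.t) == 101


def test_euler_method_close_to_rk4():
    p = lif_params()
    proto = Protocol(duration=100.0, segments=[(0.0, 100.0, 100.0)])
    a = integrate(p, None, proto, dt=0.001, method="euler")
    b = integrate(p, None, proto, dt=0.001, method="rk4")
    assert np.max(np.abs(a.V - b.V)) < 1e-3


def test_validation_errors():
    p = ELIFParams()
    with pytest.raises(ValueError):
        Protocol(duration=-1.0)
    with pytest.raises(ValueError):
        Protocol(duration=100.0, segments=[(50.0, 200.0, 10.0)])
    with pytest.raises(ValueError):
        integrate(p, None, Protocol(duration=10.0), dt=0.0)
    with pytest.raises(ValueError):
        integrate(p, None, Protocol(duration=10.0), method="leapfrog")
    with pytest.raises(ValueError):
        PoissonInput(rate=-1.0, weight=10.0)
    with pytest.raises(ValueError):
        PoissonInput(rate=1.0, weight=10.0, kind="gamma")


def test_alpha_schedule_validation_and_effect():
    p = ELIFParams(Eu=-55.0)  # integrator regime: lower alpha depolarizes
    bad = Protocol(duration=100.0, alpha_schedule=[(0.0, 1.0), (50.0, 1.5)])
    with pytest.raises(ValueError):
        integrate(p, None, bad)
    proto = Protocol(duration=2000.0,
                     alpha_schedule=[(0.0, 1.0), (1500.0, 0.4)])
    res = integrate(p, None, proto)
    assert res.eps[-1] < 0.7  # energy tracked the declining health level
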