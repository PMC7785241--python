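"""Programmatically generated test fixtures.

Everything the test suite and the CLI examples consume offline is produced
here, deterministically from a single seed:

* a current-clamp sweep set simulated from a known parameter set (total
  subthreshold conductance ``gL + a = 12 nS``, ``EL = -70 mV``) with
  additive Gaussian noise — the ground truth the fitting estimators must
  recover;
* a single-sweep file in the 3-column format from a passive cell with
  ``tau_m = 20 ms``;
* canned spike-train files with analytically known statistics: a periodic
  train (ISI CV exactly 0), a 5 Hz Poisson train over 100 s (rate within
  sampling error of 5 Hz, ISI CV near 1), and a duplicated pair of trains
  (pairwise count correlation exactly 1);
* a copy of every shipped preset configuration, so configuration-driven CLI
  paths can be exercised on plain files.

All files are small plain text with ``#`` metadata headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

from .models import ELIFParams, MAdExpParams
from .presets import _preset_dir, list_presets
from .simulate import Protocol, integrate

__all__ = [
    "make_fixtures",
    "FIT_PARAMS",
    "FIT_SINGLE_PARAMS",
    "FIT_CURRENTS",
    "FIT_STEP",
    "FIT_NOISE_SD",
]

#: ground truth of the multi-sweep fitting fixture: gL + a = 10 + 2 = 12 nS
FIT_PARAMS = MAdExpParams(
    Cm=200.0,
    gL=10.0,
    E0=-70.0,
    Eu=-70.0,
    Ef=-48.0,
    Ed=-36.0,
    Vth=-50.0,
    Vr=-58.0,
    eps0=1.0,
    epsc=0.16,
    tau_e=100.0,
    delta=0.05,
    a=2.0,
    b=0.0,
    # fast adaptation: the subthreshold response is then a single exponential
    # with conductance gL + a and effective time constant Cm / (gL + a)
    tau_w=2.0,
)

#: ground truth of the single-sweep fixture: passive cell, tau_m = Cm/gL = 20 ms
FIT_SINGLE_PARAMS = ELIFParams(
    Cm=200.0,
    gL=10.0,
    E0=-70.0,
    Eu=-70.0,
    Ef=-48.0,
    Ed=-36.0,
    Vth=-50.0,
    Vr=-58.0,
    eps0=1.0,
    epsc=0.16,
    tau_e=100.0,
    delta=0.05,
)

FIT_CURRENTS = (-60.0, -40.0, -20.0, 20.0, 40.0)  # pA, all subthreshold
FIT_STEP = (100.0, 500.0)  # ms
FIT_DURATION = 600.0  # ms
FIT_NOISE_SD = 0.3  # mV additive Gaussian measurement noise
_SAMPLE_EVERY = 2.0  # ms between written samples
_SIM_DT = 0.05  # ms integration step used to generate the traces

SPIKE_T_TOTAL = 100_000.0  # ms of canned spike trains
SPIKE_PERIOD = 500.0  # ms -> 2 Hz periodic train
SPIKE_POISSON_RATE = 5.0  # Hz


def _header(lines: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in lines.items())


def _simulate_sweep(params, amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    proto = Protocol(
        duration=FIT_DURATION,
        segments=[(FIT_STEP[0], FIT_STEP[1], amplitude)],
    )
    rec = int(round(_SAMPLE_EVERY / _SIM_DT))
    res = integrate(params, None, proto, dt=_SIM_DT, record_every=rec)
    return res.t, res.V


def write_sweep_set(path: Path, seed: int) -> None:
    """Multi-sweep file (4 columns: sweep, t_ms, V_mV, I_pA) from FIT_PARAMS."""
    rng = np.random.default_rng(seed)
    lines = [
        _header(
            {
                "fixture": "current-clamp sweep set",
                "columns": "sweep t_ms V_mV I_pA",
                "step_start_ms": FIT_STEP[0],
                "step_stop_ms": FIT_STEP[1],
                "noise_sd_mV": FIT_NOISE_SD,
                "seed": seed,
            }
        )
    ]
    for sid, amp in enumerate(FIT_CURRENTS):
        t, V = _simulate_sweep(FIT_PARAMS, amp)
        V = V + rng.normal(0.0, FIT_NOISE_SD, V.shape)
        I = np.where((t >= FIT_STEP[0]) & (t < FIT_STEP[1]), amp, 0.0)
        for ti, vi, ii in zip(t, V, I):
            lines.append(f"{sid} {ti:.1f} {vi:.4f} {ii:.1f}\n")
    path.write_text("".join(lines))


def write_single_sweep(path: Path, seed: int) -> None:
    """Single-sweep file (3 columns: t_ms, V_mV, I_pA) from FIT_SINGLE_PARAMS."""
    rng = np.random.default_rng(seed + 1)
    amp = -50.0
    t, V = _simulate_sweep(FIT_SINGLE_PARAMS, amp)
    V = V + rng.normal(0.0, FIT_NOISE_SD, V.shape)
    I = np.where((t >= FIT_STEP[0]) & (t < FIT_STEP[1]), amp, 0.0)
    lines = [
        _header(
            {
                "fixture": "single current-clamp sweep",
                "columns": "t_ms V_mV I_pA",
                "step_start_ms": FIT_STEP[0],
                "step_stop_ms": FIT_STEP[1],
                "noise_sd_mV": FIT_NOISE_SD,
                "seed": seed,
            }
        )
    ]
    for ti, vi, ii in zip(t, V, I):
        lines.append(f"{ti:.1f} {vi:.4f} {ii:.1f}\n")
    path.write_text("".join(lines))


def _write_trains(path: Path, trains: list[np.ndarray], note: str, seed: int) -> None:
    lines = [
        _header(
            {
                "fixture": note,
                "columns": "neuron_id time_ms",
                "duration_ms": SPIKE_T_TOTAL,
                "seed": seed,
            }
        )
    ]
    for i, tr in enumerate(trains):
        for ts in tr:
            lines.append(f"{i} {ts:.3f}\n")
    path.write_text("".join(lines))


def write_spike_trains(out_dir: Path, seed: int) -> dict:
    """Three canned spike-train files with known statistics."""
    rng = np.random.default_rng(seed + 2)
    periodic = np.arange(SPIKE_PERIOD / 2.0, SPIKE_T_TOTAL, SPIKE_PERIOD)
    # exponential inter-spike intervals -> homogeneous Poisson process
    mean_isi = 1000.0 / SPIKE_POISSON_RATE
    n_max = int(SPIKE_T_TOTAL / mean_isi * 3)
    poisson = np.cumsum(rng.exponential(mean_isi, n_max))
    poisson = poisson[poisson < SPIKE_T_TOTAL]

    paths = {
        "spikes_periodic": out_dir / "spikes_periodic.txt",
        "spikes_poisson": out_dir / "spikes_poisson.txt",
        "spikes_duplicated": out_dir / "spikes_duplicated.txt",
    }
    _write_trains(
        paths["spikes_periodic"], [periodic], "periodic train (ISI CV = 0)", seed
    )
    _write_trains(
        paths["spikes_poisson"], [poisson], "5 Hz Poisson train", seed
    )
    _write_trains(
        paths["spikes_duplicated"],
        [poisson, poisson.copy()],
        "duplicated Poisson pair (count correlation = 1)",
        seed,
    )
    return paths


def read_spike_file(path) -> list[np.ndarray]:
    """Read a two-column (neuron_id, time_ms) spike file into per-id trains."""
    ids: list[int] = []
    times: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()
        ids.append(int(float(a)))
        times.append(float(b))
    n = max(ids) + 1 if ids else 0
    ids_arr = np.asarray(ids)
    times_arr = np.asarray(times)
    return [np.sort(times_arr[ids_arr == i]) for i in range(n)]


def make_fixtures(seed: int = 0, out_dir: Union[str, Path] = "fixtures") -> dict:
    """Generate all fixtures under ``out_dir``; returns {name: Path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    p = out_dir / "fit_sweeps.txt"
    write_sweep_set(p, seed)
    manifest["fit_sweeps"] = p

    p = out_dir / "fit_single_sweep.txt"
    write_single_sweep(p, seed)
    manifest["fit_single_sweep"] = p

    manifest.update(write_spike_trains(out_dir, seed))

    cfg_dir = out_dir / "configs"
    cfg_dir.mkdir(exist_ok=True)
    for name in list_presets():
        dst = cfg_dir / f"{name}.yaml"
        dst.write_text((_preset_dir() / f"{name}.yaml").read_text())
        manifest[f"config_{name}"] = dst
    return manifest
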