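"""YAML configuration handling: serialize and deserialize parameter sets,
protocols and network specifications with strict validation.

Every ``*_from_dict`` function rejects unknown keys by name so that typos in
user-written configuration files fail loudly instead of being ignored.  The
``*_to_dict`` functions produce plain-scalar dictionaries that round-trip
exactly through :func:`load_config` / :func:`dump_config`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .errors import ConfigError
from .models import ELIFParams, MAdExpParams, Params
from .network import HomeostasisEntry, NetworkSpec, StimulusSpec
from .simulate import PoissonInput, Protocol

__all__ = [
    "params_from_dict",
    "params_to_dict",
    "protocol_from_dict",
    "protocol_to_dict",
    "network_spec_from_dict",
    "network_spec_to_dict",
    "load_config",
    "dump_config",
    "default_protocol",
]

#: protocol used when a configuration omits one: one second, no input
DEFAULT_PROTOCOL_DURATION = 1000.0


def default_protocol() -> Protocol:
    """One second of unperturbed dynamics (no current, no noise)."""
    return Protocol(duration=DEFAULT_PROTOCOL_DURATION)


def _check_keys(d: dict, allowed: set[str], context: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(d).__name__}")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _field_names(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def params_from_dict(d: dict) -> Params:
    """Build a parameter set from a mapping with a ``model`` discriminator.

    ``model`` must be ``"elif"`` or ``"madexp"``; the remaining keys are the
    dataclass fields.  Dataclass validation errors are re-raised as
    :class:`~metaneuron.errors.ConfigError`.
    """
    if not isinstance(d, dict):
        raise ConfigError(f"params: expected a mapping, got {type(d).__name__}")
    model = d.get("model")
    if model not in ("elif", "madexp"):
        raise ConfigError(
            f"params: 'model' must be 'elif' or 'madexp', got {model!r}"
        )
    cls = ELIFParams if model == "elif" else MAdExpParams
    _check_keys(d, _field_names(cls) | {"model"}, "params")
    kwargs = {k: v for k, v in d.items() if k != "model"}
    for k, v in kwargs.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"params: field '{k}' must be a number, got {v!r}")
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"params: {exc}") from exc


def params_to_dict(p: Params) -> dict:
    d: dict[str, Any] = {
        "model": "madexp" if isinstance(p, MAdExpParams) else "elif"
    }
    d.update(dataclasses.asdict(p))
    return d


def _poisson_from_dict(d: dict) -> PoissonInput:
    _check_keys(d, {"rate", "weight", "kind", "tau_syn"}, "protocol.poisson")
    try:
        return PoissonInput(**d)
    except ValueError as exc:
        raise ConfigError(f"protocol.poisson: {exc}") from exc


def protocol_from_dict(d: Optional[dict]) -> Protocol:
    """Build a protocol; ``None`` or ``{}`` yields :func:`default_protocol`.

    ``segments`` entries are ``[start_ms, stop_ms, amplitude_pA]`` triples and
    ``alpha_schedule`` entries are ``[t_ms, alpha]`` pairs.
    """
    if not d:
        return default_protocol()
    _check_keys(
        d, {"duration", "segments", "poisson", "alpha_schedule"}, "protocol"
    )
    duration = d.get("duration", DEFAULT_PROTOCOL_DURATION)
    segments = []
    for i, seg in enumerate(d.get("segments") or []):
        if not (isinstance(seg, (list, tuple)) and len(seg) == 3):
            raise ConfigError(
                f"protocol.segments[{i}]: expected [start, stop, amplitude]"
            )
        segments.append(tuple(float(x) for x in seg))
    schedule = None
    if d.get("alpha_schedule") is not None:
        schedule = []
        for i, knot in enumerate(d["alpha_schedule"]):
            if not (isinstance(knot, (list, tuple)) and len(knot) == 2):
                raise ConfigError(
                    f"protocol.alpha_schedule[{i}]: expected [t_ms, alpha]"
                )
            schedule.append((float(knot[0]), float(knot[1])))
    poisson = _poisson_from_dict(d["poisson"]) if d.get("poisson") else None
    try:
        return Protocol(
            duration=float(duration),
            segments=tuple(segments),
            poisson=poisson,
            alpha_schedule=schedule,
        )
    except ValueError as exc:
        raise ConfigError(f"protocol: {exc}") from exc


def protocol_to_dict(proto: Protocol) -> dict:
    d: dict[str, Any] = {"duration": proto.duration}
    if proto.segments:
        d["segments"] = [list(s) for s in proto.segments]
    if proto.poisson is not None:
        d["poisson"] = dataclasses.asdict(proto.poisson)
    if proto.alpha_schedule is not None:
        d["alpha_schedule"] = [list(k) for k in proto.alpha_schedule]
    return d


def network_spec_from_dict(d: dict) -> NetworkSpec:
    """Build a network specification, including the nested stimulus and
    homeostasis table."""
    allowed = _field_names(NetworkSpec)
    _check_keys(d, allowed, "network")
    kwargs = dict(d)
    if kwargs.get("stimulus") is not None:
        s = kwargs["stimulus"]
        _check_keys(s, _field_names(StimulusSpec), "network.stimulus")
        window = s.get("window")
        if window is not None:
            s = dict(s, window=tuple(float(x) for x in window))
        kwargs["stimulus"] = StimulusSpec(**s)
    if kwargs.get("homeostasis") is not None:
        entries = []
        for i, e in enumerate(kwargs["homeostasis"]):
            _check_keys(e, _field_names(HomeostasisEntry), f"network.homeostasis[{i}]")
            entries.append(HomeostasisEntry(**e))
        kwargs["homeostasis"] = tuple(entries)
    try:
        return NetworkSpec(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"network: {exc}") from exc


def network_spec_to_dict(spec: NetworkSpec) -> dict:
    d = dataclasses.asdict(spec)
    if spec.stimulus is not None:
        d["stimulus"] = dict(
            dataclasses.asdict(spec.stimulus),
            window=list(spec.stimulus.window),
        )
    d["homeostasis"] = [dataclasses.asdict(e) for e in spec.homeostasis]
    return d


def load_config(path: Union[str, Path]) -> dict:
    """Load a simulation configuration file.

    The file is a mapping with keys among ``params`` (required),
    ``protocol``, ``protocols`` (a mapping of named protocols), ``network``
    and ``name``/``notes`` (free-text metadata).  Returns a dictionary with
    the parsed objects: ``{"params": Params, "protocol": Protocol,
    "protocols": {name: Protocol}, "network": NetworkSpec | None, ...}``.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    return parse_config(raw, context=str(path))


def parse_config(raw: Any, context: str = "config") -> dict:
    """Parse an already-loaded configuration mapping (see :func:`load_config`)."""
    if not isinstance(raw, dict):
        raise ConfigError(f"{context}: top level must be a mapping")
    _check_keys(
        raw,
        {"name", "notes", "params", "protocol", "protocols", "network"},
        context,
    )
    if "params" not in raw:
        raise ConfigError(f"{context}: missing required key 'params'")
    out: dict[str, Any] = {
        "name": raw.get("name"),
        "notes": raw.get("notes"),
        "params": params_from_dict(raw["params"]),
        "protocol": protocol_from_dict(raw.get("protocol")),
        "protocols": {
            str(k): protocol_from_dict(v)
            for k, v in (raw.get("protocols") or {}).items()
        },
        "network": (
            network_spec_from_dict(raw["network"]) if raw.get("network") else None
        ),
    }
    return out


def dump_config(
    path: Union[str, Path],
    params: Params,
    protocol: Optional[Protocol] = None,
    network: Optional[NetworkSpec] = None,
    name: Optional[str] = None,
) -> None:
    """Write a configuration file that :func:`load_config` round-trips."""
    doc: dict[str, Any] = {}
    if name:
        doc["name"] = name
    doc["params"] = params_to_dict(params)
    if protocol is not None:
        doc["protocol"] = protocol_to_dict(protocol)
    if network is not None:
        doc["network"] = network_spec_to_dict(network)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
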