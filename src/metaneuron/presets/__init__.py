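"""Built-in parameter presets.

Presets are YAML files shipped inside the package (``metaneuron/presets/``)
and parsed with the same strict machinery as user configuration files, so
each preset doubles as a format example.  A preset bundles a parameter set
with optional named protocols and an optional network specification.

Use :func:`list_presets` to enumerate them and :func:`load_preset` to fetch
one; ``load_preset(name)["params"]`` is the parameter object.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import yaml

from ..config import parse_config
from ..errors import ConfigError
from ..models import Params
from ..network import NetworkSpec
from ..simulate import Protocol

__all__ = [
    "list_presets",
    "load_preset",
    "preset_params",
    "preset_protocol",
    "preset_network",
]

def _preset_dir():
    return resources.files(__name__)


def list_presets() -> list[str]:
    """Names of all shipped presets, sorted."""
    names = [
        entry.name[: -len(".yaml")]
        for entry in _preset_dir().iterdir()
        if entry.name.endswith(".yaml")
    ]
    return sorted(names)


def load_preset(name: str) -> dict:
    """Load and parse a shipped preset by name.

    Returns the same structure as :func:`metaneuron.config.load_config`.
    Raises :class:`~metaneuron.errors.ConfigError` for unknown names.
    """
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except (FileNotFoundError, OSError) as exc:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from exc
    return parse_config(yaml.safe_load(text), context=f"preset {name!r}")


def preset_params(name: str) -> Params:
    """Parameter set of a preset."""
    return load_preset(name)["params"]


def preset_protocol(name: str, key: Optional[str] = None) -> Protocol:
    """A protocol shipped with a preset.

    With ``key=None`` returns the preset's default protocol; otherwise looks
    up the named entry in its ``protocols`` table.
    """
    cfg = load_preset(name)
    if key is None:
        return cfg["protocol"]
    try:
        return cfg["protocols"][key]
    except KeyError as exc:
        raise ConfigError(
            f"preset {name!r} has no protocol {key!r}; "
            f"available: {', '.join(sorted(cfg['protocols']))}"
        ) from exc


def preset_network(name: str) -> NetworkSpec:
    """Network specification of a preset (raises if it has none)."""
    net = load_preset(name)["network"]
    if net is None:
        raise ConfigError(f"preset {name!r} has no network specification")
    return net
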