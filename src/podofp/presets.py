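"""Named kinetic parameter sets keyed by the regime they exhibit.

``fig2C`` is the calibrated healthy baseline; the other sets change only the
printed anchors: ``fig2D`` lowers the positive feedback (alpha_f 0.32->0.1),
``fig2E`` raises bundling (alpha_b 0.03->0.05) and ``fig2F`` combines both.
``S3``/``S4`` are aliases for the supplementary phase-plane sets.  Sets can
be round-tripped through YAML/JSON for use as run configs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .kinetics import KineticParams, calibrated_params

_ALPHA_F_LOW = 0.10
_ALPHA_B_HIGH = 0.05

_VARIANTS: dict[str, dict[str, float]] = {
    "fig2C": {},
    "fig2D": {"alpha_f": _ALPHA_F_LOW},
    "fig2E": {"alpha_b": _ALPHA_B_HIGH},
    "fig2F": {"alpha_f": _ALPHA_F_LOW, "alpha_b": _ALPHA_B_HIGH},
}
_ALIASES = {"S3": "fig2E", "S4": "fig2D"}


def preset_names() -> list[str]:
    return sorted(_VARIANTS) + sorted(_ALIASES)


def get_params(name: str) -> KineticParams:
    """Parameter set for a named regime (e.g. ``fig2C``)."""
    key = _ALIASES.get(name, name)
    if key not in _VARIANTS:
        raise KeyError(
            f"unknown parameter set {name!r}; choose from {preset_names()}")
    return calibrated_params().replace(**_VARIANTS[key])


def params_to_dict(p: KineticParams) -> dict:
    return dataclasses.asdict(p)


def params_from_dict(d: dict) -> KineticParams:
    return KineticParams(**d)


def dump_params(p: KineticParams, path: str | Path) -> None:
    path = Path(path)
    data = params_to_dict(p)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def load_params(source: str | Path) -> KineticParams:
    """Load a set by preset name or from a YAML/JSON file path."""
    key = str(source)
    if key in _VARIANTS or key in _ALIASES:
        return get_params(key)
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return params_from_dict(data)
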