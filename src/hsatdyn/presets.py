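"""Registry of calibrated parameter presets shipped with the package.

Presets are YAML files under ``hsatdyn/_data``; each was produced by the
calibration procedure in :mod:`hsatdyn.calibrate` and is frozen here so
analyses are reproducible without re-running the search.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .params import ModelParameters

__all__ = ["get_preset", "list_presets"]


def list_presets() -> list[str]:
    """Names of the shipped parameter presets."""
    root = resources.files("hsatdyn") / "_data"
    return sorted(
        p.name[: -len(".yaml")]
        for p in root.iterdir()
        if p.name.endswith(".yaml")
    )


def get_preset(name: str) -> ModelParameters:
    """Load a shipped preset (``"reference"`` or ``"bistable"``) by name."""
    path = resources.files("hsatdyn") / "_data" / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    return ModelParameters.from_dict(data)
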