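"""YAML configuration loading: every model parameter is overridable."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .geometry import AnatomySpec, ImplantSpec
from .sweep import SweepConfig

__all__ = ["load_config", "dump_config"]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> SweepConfig:
    """Build a :class:`SweepConfig` from a YAML file and/or override dict.

    Recognised top-level keys: ``anatomy``, ``implant``, and any
    :class:`SweepConfig` field (``versions``, ``cup_poses``, ``load_names``,
    ``mesh_resolution``, ``sweep_step``, ``n_elements``,
    ``foundation_mode``, ``calibration``, ``support_thickness``).
    """
    data: dict = {}
    if path is not None:
        data.update(yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        data.update(overrides)
    anatomy = AnatomySpec(**data.pop("anatomy", {}))
    implant = ImplantSpec(**data.pop("implant", {}))
    if "versions" in data:
        data["versions"] = tuple(float(v) for v in data["versions"])
    if "cup_poses" in data:
        data["cup_poses"] = tuple((float(i), float(v)) for i, v in data["cup_poses"])
    if "load_names" in data:
        data["load_names"] = tuple(data["load_names"])
    if "calibration" in data and "cup" in data["calibration"]:
        data["calibration"] = dict(
            data["calibration"], cup=tuple(data["calibration"]["cup"])
        )
    unknown = set(data) - set(SweepConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SweepConfig(anatomy=anatomy, implant=implant, **data)


def dump_config(config: SweepConfig, path: str | Path) -> None:
    d = {
        "anatomy": asdict(config.anatomy),
        "implant": asdict(config.implant),
        "versions": list(config.versions),
        "cup_poses": [list(p) for p in config.cup_poses],
        "load_names": list(config.load_names),
        "mesh_resolution": config.mesh_resolution,
        "sweep_step": config.sweep_step,
        "n_elements": config.n_elements,
        "foundation_mode": config.foundation_mode,
        "calibration": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.calibration.items()
        },
        "support_thickness": config.support_thickness,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
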