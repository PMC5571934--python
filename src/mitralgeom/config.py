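"""YAML run configuration with strict schema validation.

Unspecified fields take the model's canonical defaults, so an empty
file is a complete configuration for the default valve.  Unknown keys
are rejected with the offending path.  Lengths are centimetres; angles
are radians unless written as a mapping ``{value: ..., unit: deg}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .meshing import MeshResolution
from .valve_model import (
    AnnulusGeometry,
    DEFAULT_JUNCTION_PHASE,
    InvalidParameterError,
    LeafletDimensions,
    ValveParameters,
)

__all__ = ["RunConfig", "ConfigError", "read_config", "write_config"]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs: valve parameters, resolution, output, cohort."""

    params: ValveParameters = field(default_factory=ValveParameters)
    resolution: MeshResolution = field(default_factory=MeshResolution)
    output_path: str = "valve.stl"
    output_format: str = "stl"
    scale_to_mm: bool = False
    cohort: CohortSpec = field(default_factory=CohortSpec)


_SCHEMA = {
    "annulus": {"ic", "sl_ant", "sl_post"},
    "leaflets": {"h_ant", "h_p1", "h_p2", "h_p3", "w_ant", "w_p1", "w_p2", "w_p3"},
    "junction_phase": None,  # scalar or {value, unit}
    "mesh": {"n_u", "n_v"},
    "output": {"path", "format", "scale_to_mm"},
    "cohort": {"n", "seed", "distribution", "annulus_jitter"},
}


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _parse_angle(raw) -> float:
    """Radians from a scalar, or from ``{value: ..., unit: rad|deg}``."""
    if isinstance(raw, dict):
        _check_keys("junction_phase", raw, {"value", "unit"})
        if "value" not in raw:
            raise ConfigError("junction_phase mapping needs a 'value' key")
        unit = raw.get("unit", "rad")
        if unit not in ("rad", "deg"):
            raise ConfigError(f"angle unit must be 'rad' or 'deg', got {unit!r}")
        value = float(raw["value"])
        return math.radians(value) if unit == "deg" else value
    return float(raw)


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a :class:`RunConfig` from a (possibly empty) mapping."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    _check_keys("root", data, set(_SCHEMA))

    try:
        ann_raw = data.get("annulus", {}) or {}
        _check_keys("annulus", ann_raw, _SCHEMA["annulus"])
        annulus = AnnulusGeometry(**{k: float(v) for k, v in ann_raw.items()})

        dims_raw = data.get("leaflets", {}) or {}
        _check_keys("leaflets", dims_raw, _SCHEMA["leaflets"])
        dims = LeafletDimensions(**{k: float(v) for k, v in dims_raw.items()})

        phi = (
            _parse_angle(data["junction_phase"])
            if "junction_phase" in data
            else DEFAULT_JUNCTION_PHASE
        )
        params = ValveParameters(annulus=annulus, dims=dims, phi=phi)
        params.partition  # validate feasibility eagerly

        mesh_raw = data.get("mesh", {}) or {}
        _check_keys("mesh", mesh_raw, _SCHEMA["mesh"])
        resolution = MeshResolution(**{k: int(v) for k, v in mesh_raw.items()})

        out_raw = data.get("output", {}) or {}
        _check_keys("output", out_raw, _SCHEMA["output"])

        cohort_raw = data.get("cohort", {}) or {}
        _check_keys("cohort", cohort_raw, _SCHEMA["cohort"])
        cohort = CohortSpec(phi=phi, **cohort_raw)
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        params=params,
        resolution=resolution,
        output_path=str(out_raw.get("path", "valve.stl")),
        output_format=str(out_raw.get("format", "stl")),
        scale_to_mm=bool(out_raw.get("scale_to_mm", False)),
        cohort=cohort,
    )


def config_to_dict(cfg: RunConfig) -> dict:
    p, a, d = cfg.params, cfg.params.annulus, cfg.params.dims
    return {
        "annulus": {"ic": a.ic, "sl_ant": a.sl_ant, "sl_post": a.sl_post},
        "leaflets": {
            "h_ant": d.h_ant,
            "h_p1": d.h_p1,
            "h_p2": d.h_p2,
            "h_p3": d.h_p3,
            "w_ant": d.w_ant,
            "w_p1": d.w_p1,
            "w_p2": d.w_p2,
            "w_p3": d.w_p3,
        },
        "junction_phase": p.phi,
        "mesh": {"n_u": cfg.resolution.n_u, "n_v": cfg.resolution.n_v},
        "output": {
            "path": cfg.output_path,
            "format": cfg.output_format,
            "scale_to_mm": cfg.scale_to_mm,
        },
        "cohort": {
            "n": cfg.cohort.n,
            "seed": cfg.cohort.seed,
            "distribution": cfg.cohort.distribution,
            "annulus_jitter": cfg.cohort.annulus_jitter,
        },
    }


def read_config(path: str | Path | None) -> RunConfig:
    """Read a YAML configuration file; ``None`` yields all defaults."""
    if path is None:
        return config_from_dict({})
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    return config_from_dict(data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a configuration; reading it back yields an identical config."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
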