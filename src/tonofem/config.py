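"""YAML configuration loading for the command-line interface.

Sections: ``geometry`` (ocular dimensions), ``materials`` (per-tissue E,
nu, density), ``probe`` (diameter or preset name), ``sweep`` (grids) and
``solver`` (resolution preset, constraint mode, increments).  Every field
is optional; omitted values fall back to the study defaults.
"""

from __future__ import annotations

import yaml

from tonofem.fem import IsotropicMaterial, default_materials
from tonofem.geometry import OcularGeometryParams, PROBE_PRESETS, ProbeSpec
from tonofem.pipeline import SweepConfig

__all__ = ["load_config", "sweep_config_from_dict"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def geometry_from_dict(d: dict | None) -> OcularGeometryParams:
    return OcularGeometryParams(**(d or {}))


def materials_from_dict(d: dict | None) -> dict[str, IsotropicMaterial]:
    mats = default_materials()
    for name, spec in (d or {}).items():
        mats[name] = IsotropicMaterial(
            young_modulus=float(spec["young_modulus"]),
            poisson_ratio=float(spec["poisson_ratio"]),
            density=spec.get("density"),
            name=name,
        )
    return mats


def probe_from_value(v) -> ProbeSpec:
    if isinstance(v, str):
        return PROBE_PRESETS[v]
    if isinstance(v, dict):
        return ProbeSpec(**v)
    return ProbeSpec(diameter=float(v))


def sweep_config_from_dict(cfg: dict) -> tuple[SweepConfig, dict]:
    """(SweepConfig, materials) from a parsed config mapping."""
    geometry = geometry_from_dict(cfg.get("geometry"))
    materials = materials_from_dict(cfg.get("materials"))
    sweep = cfg.get("sweep", {})
    solver = cfg.get("solver", {})
    probes = sweep.get("probes")
    if probes is None and "probe" in cfg:
        probes = [cfg["probe"]]
    kwargs = dict(geometry=geometry)
    if probes is not None:
        kwargs["probes"] = tuple(probe_from_value(p) for p in probes)
    if "depths_mm" in sweep:
        kwargs["depths_mm"] = tuple(float(v) for v in sweep["depths_mm"])
    if "iops_mmhg" in sweep:
        kwargs["iops_mmhg"] = tuple(float(v) for v in sweep["iops_mmhg"])
    if "resolution" in solver:
        kwargs["resolution"] = solver["resolution"]
    if "constraint_mode" in solver:
        kwargs["constraint_mode"] = solver["constraint_mode"]
    if "n_increments" in solver:
        kwargs["n_increments"] = int(solver["n_increments"])
    if "outdir" in cfg:
        kwargs["outdir"] = cfg["outdir"]
    return SweepConfig(**kwargs), materials
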