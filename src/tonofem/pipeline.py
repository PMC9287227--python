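"""Sweep orchestration: force-depth-IOP tables, linear force relations and
output writing.

A sweep builds the eye mesh once, factorises the stiffness once and solves
every (probe, IOP, depth) grid point against that factorisation; the
pipeline is fully deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tonofem import fem as F
from tonofem.contact import IndentationSolver
from tonofem.geometry import (
    OcularGeometryParams,
    PROBE_PRESETS,
    ProbeSpec,
    build_eye_shell,
)
from tonofem.meshing import RESOLUTION_PRESETS, ShellMesh, sweep_shell_mesh

__all__ = [
    "SweepConfig",
    "SweepTable",
    "ForceRelations",
    "run_sweep",
    "fit_force_relations",
    "summarize_fields",
    "write_outputs",
]

log = logging.getLogger("tonofem")

SWEEP_COLUMNS = [
    "probe_diameter_mm",
    "iop_mmhg",
    "depth_mm",
    "force_N",
    "max_total_deformation_mm",
    "max_von_mises_MPa",
    "max_stress_region",
    "converged",
]


@dataclass(frozen=True)
class SweepConfig:
    """Grid definition for a tonometry sweep.

    Defaults reproduce the study conditions: plunging depths 0.3-0.7 mm in
    0.1 mm steps, IOP 10/15/20 mmHg, the standard 1.7 mm probe, ten
    displacement increments per point.
    """

    depths_mm: tuple = (0.3, 0.4, 0.5, 0.6, 0.7)
    iops_mmhg: tuple = (10.0, 15.0, 20.0)
    probes: tuple = ("standard",)
    resolution: str = "reference"
    constraint_mode: str = "remote-rigid-body"
    n_increments: int = 10
    geometry: OcularGeometryParams = field(default_factory=OcularGeometryParams)
    outdir: str | None = None
    export_fields: bool = False

    def __post_init__(self) -> None:
        for name, grid in (("depths", self.depths_mm), ("iops", self.iops_mmhg)):
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} grid must be nonempty, strictly increasing")
        if min(self.depths_mm) <= 0:
            raise ValueError("depths must be positive")
        if not self.probes:
            raise ValueError("at least one probe is required")

    def probe_specs(self) -> list[ProbeSpec]:
        out = []
        for p in self.probes:
            if isinstance(p, ProbeSpec):
                out.append(p)
            elif isinstance(p, str):
                out.append(PROBE_PRESETS[p])
            else:
                out.append(ProbeSpec(diameter=float(p)))
        return out


@dataclass
class SweepTable:
    """Force-depth-IOP results, one row per grid point."""

    frame: pd.DataFrame
    config: SweepConfig

    def __post_init__(self) -> None:
        self.frame = self.frame.sort_values(
            ["probe_diameter_mm", "iop_mmhg", "depth_mm"]
        ).reset_index(drop=True)

    def force(self, probe_diameter: float, iop: float, depth: float) -> float:
        f = self.frame
        row = f[
            (np.isclose(f.probe_diameter_mm, probe_diameter))
            & (np.isclose(f.iop_mmhg, iop))
            & (np.isclose(f.depth_mm, depth))
        ]
        if len(row) != 1:
            raise KeyError(f"no unique row for ({probe_diameter}, {iop}, {depth})")
        return float(row.force_N.iloc[0])


@dataclass
class ForceRelations:
    """Linear force relations extracted from a sweep.

    ``per_iop`` maps IOP (mmHg) to (intercept N, slope N/mm, R^2) of the
    force-depth fit; ``dF_dIOP`` is the mean finite-difference IOP
    sensitivity (N per mmHg) averaged over the depth grid, and
    ``slope_per_5mmhg`` expresses it per 5 mmHg.
    """

    per_iop: dict
    dF_dIOP: float
    slope_per_5mmhg: float

    def to_dict(self) -> dict:
        return {
            "per_iop": {
                str(k): {"intercept_N": v[0], "slope_N_per_mm": v[1], "r2": v[2]}
                for k, v in self.per_iop.items()
            },
            "dF_dIOP_N_per_mmHg": self.dF_dIOP,
            "slope_per_5mmHg_N": self.slope_per_5mmhg,
        }


def build_sweep_mesh(config: SweepConfig) -> ShellMesh:
    na, nm, nt, order = RESOLUTION_PRESETS[config.resolution]
    shell = build_eye_shell(config.geometry)
    return sweep_shell_mesh(shell, na, nm, nt, order=order)


def run_sweep(
    config: SweepConfig,
    mesh: ShellMesh | None = None,
    solver: IndentationSolver | None = None,
    materials: dict | None = None,
    keep_results: bool = False,
) -> SweepTable:
    """Solve every grid point of the sweep.

    The mesh is built once and shared; a non-converged point is recorded
    with converged=False and the sweep continues.  Deterministic: identical
    configs produce identical tables.
    """
    t0 = time.time()
    materials = materials or F.default_materials()
    if solver is None:
        if mesh is None:
            mesh = build_sweep_mesh(config)
        solver = IndentationSolver(mesh, materials, config.constraint_mode)
    mesh = solver.mesh
    rows = []
    results = {}
    failures = []
    for probe in config.probe_specs():
        for iop in config.iops_mmhg:
            for depth in config.depths_mm:
                case = F.LoadCase(
                    iop_mmhg=iop, probe=probe, target_depth=depth,
                    n_increments=config.n_increments,
                    constraint_mode=config.constraint_mode,
                )
                try:
                    res = solver.solve(case)
                    dmax, _ = res.max_total_deformation
                    vmax, region = res.max_von_mises
                    rows.append(
                        (probe.diameter, iop, depth, res.reaction_force,
                         dmax, vmax, region, True)
                    )
                    if keep_results:
                        results[(probe.diameter, iop, depth)] = res
                    log.info(
                        "point d=%.2f iop=%g probe=%.2f -> F=%.6f N",
                        depth, iop, probe.diameter, res.reaction_force,
                    )
                except Exception as exc:  # noqa: BLE001 - record and continue
                    rows.append(
                        (probe.diameter, iop, depth, np.nan, np.nan, np.nan,
                         "", False)
                    )
                    failures.append(((probe.diameter, iop, depth), str(exc)))
                    log.warning("point (%s, %s, %s) failed: %s",
                                probe.diameter, iop, depth, exc)
    frame = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    table = SweepTable(frame=frame, config=config)
    if failures:
        log.warning("sweep finished with %d failed points", len(failures))
    log.info("sweep of %d points in %.1f s", len(rows), time.time() - t0)
    table.results = results
    table.failures = failures
    return table


def fit_force_relations(table: SweepTable) -> ForceRelations:
    """Ordinary least-squares force-depth line per IOP level plus the mean
    finite-difference IOP sensitivity (expressed per 5 mmHg)."""
    f = table.frame[table.frame.converged]
    # restrict to the first probe for the relations (the default sweep has one)
    d0 = f.probe_diameter_mm.iloc[0]
    f = f[np.isclose(f.probe_diameter_mm, d0)]
    depths = np.sort(f.depth_mm.unique())
    iops = np.sort(f.iop_mmhg.unique())
    if len(depths) < 2 or len(iops) < 2:
        raise ValueError("need at least 2 depths and 2 IOP levels to fit")
    per_iop = {}
    for iop in iops:
        sub = f[np.isclose(f.iop_mmhg, iop)].sort_values("depth_mm")
        x, y = sub.depth_mm.to_numpy(), sub.force_N.to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        yhat = intercept + slope * x
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        per_iop[float(iop)] = (float(intercept), float(slope), float(r2))
    # finite differences across the IOP grid, averaged over depths
    sens = []
    for depth in depths:
        sub = f[np.isclose(f.depth_mm, depth)].sort_values("iop_mmhg")
        dF = np.diff(sub.force_N.to_numpy())
        dI = np.diff(sub.iop_mmhg.to_numpy())
        sens.extend(dF / dI)
    dF_dIOP = float(np.mean(sens))
    return ForceRelations(
        per_iop=per_iop, dF_dIOP=dF_dIOP, slope_per_5mmhg=5.0 * dF_dIOP
    )


def summarize_fields(result) -> dict:
    """Maximum total deformation (+ location) and maximum von Mises
    stress (+ region tag) of a converged solve."""
    dmax, loc = result.max_total_deformation
    vmax, region = result.max_von_mises
    return {
        "max_total_deformation_mm": dmax,
        "max_deformation_location_mm": [float(v) for v in loc],
        "max_von_mises_MPa": vmax,
        "max_stress_region": region,
    }


def write_outputs(table: SweepTable, relations: ForceRelations | None,
                  outdir, results: dict | None = None) -> dict:
    """Write sweep CSV, relations JSON, run metadata and optional VTU
    fields; returns the mapping of written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    csv_path = out / "sweep.csv"
    with open(csv_path, "w") as fh:
        fh.write("# tonofem sweep table; units: mm, mmHg, N, MPa\n")
        table.frame.to_csv(fh, index=False, float_format="%.9g")
    paths["sweep"] = csv_path
    if relations is not None:
        rel_path = out / "relations.json"
        rel_path.write_text(json.dumps(relations.to_dict(), indent=2) + "\n")
        paths["relations"] = rel_path
    from tonofem import __version__ as _version

    cfg = asdict(table.config)
    cfg["geometry"] = asdict(table.config.geometry)
    meta = {
        "tonofem_version": _version,
        "units": {"length": "mm", "force": "N", "stress": "MPa",
                  "pressure_input": "mmHg"},
        "config": _jsonable(cfg),
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["metadata"] = meta_path
    log_lines = [
        f"tonofem sweep: {len(table.frame)} grid points, "
        f"{int(table.frame.converged.sum())} converged",
    ]
    for _, row in table.frame.iterrows():
        log_lines.append(
            f"probe {row.probe_diameter_mm:g} mm  IOP {row.iop_mmhg:g} mmHg  "
            f"depth {row.depth_mm:g} mm -> force {row.force_N:.6f} N  "
            f"converged={bool(row.converged)}"
        )
    for point, msg in getattr(table, "failures", []):
        log_lines.append(f"FAILED {point}: {msg}")
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    paths["log"] = log_path
    if results:
        for (dia, iop, depth), res in results.items():
            name = f"fields_d{dia:g}_iop{iop:g}_h{depth:g}.vtu"
            pd_data = {
                "displacement_mm": res.u.reshape(-1, 3),
                "total_deformation_mm": res.stress.total_deformation,
            }
            cd = {"von_mises_MPa": res.stress.von_mises}
            res.mesh.write_vtu(out / name, point_data=pd_data, cell_data=cd)
            paths[name] = out / name
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, ProbeSpec):
        return asdict(obj)
    return obj
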