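"""YAML run configuration: schema, loading and the end-to-end pipeline.

A run config gathers the phantom (or mask path), the needle-plan parameters,
material constants, the insertion rule and the solver settings. Every default
of the simulator is exposed here. Example::

    phantom:
      prostate_semi_axes: [20, 15, 15]
      block_dims: [80, 80, 80]
      nodal_spacing: 5.0
      rng_seed: 0
    # or: mask: {path: prostate.nii.gz, spacing: 5.0, margin: 20.0}
    plan:
      n_anchor: 2
      n_catheter: 17
      template_pitch: 5.0
      sequence: alternate_lb_rt
    materials:
      prostate:    {young_kpa: 25.0, poisson: 0.49, density: 1000.0}
      surrounding: {young_kpa: 10.0, poisson: 0.49, density: 1000.0}
    insertion:
      influence_radius: 3.0
      decay: linear
      increment: 2.0
      stiffening_factor: 30.0
      catheter_stiffening_radius: 2.0
      anchor_stiffening: true
    solver:
      dilation: 2.0
      safety: 0.5
      relax_tol: 1.0e-3
      max_iter: 3000
      window: 50
      mass_scaling: true
    output:
      voxel_size: 1.0
      write_vtk: true
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .constitutive import Material
from .errors import InputError
from .evaluation import (dice, inplane_displacement_stats,
                         prostate_centroid_displacement, voxelize_region)
from .insertion import InsertionConfig, SolverConfig, run_procedure
from .masks import read_mask
from .phantom import (REGION_PROSTATE, REGION_SURROUNDING, PhantomSpec,
                      domain_from_mask, generate_needle_plan, generate_phantom)

__all__ = ["RunConfig", "load_config", "run_from_config"]


@dataclass
class RunConfig:
    phantom: PhantomSpec | None
    mask: dict | None
    plan: dict
    materials: dict
    insertion: InsertionConfig
    anchor_stiffening: bool
    solver: SolverConfig
    output: dict


def _material(d: dict) -> Material:
    if "young_kpa" in d:
        return Material.from_young_poisson(float(d["young_kpa"]),
                                           float(d.get("poisson", 0.49)),
                                           float(d.get("density", 1000.0)))
    return Material(float(d["shear_kpa"]), float(d["bulk_kpa"]),
                    float(d.get("density", 1000.0)))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InputError(f"config {path} is not a mapping")
    phantom = None
    mask = raw.get("mask")
    if "phantom" in raw:
        p = dict(raw["phantom"])
        phantom = PhantomSpec(
            prostate_semi_axes=tuple(p.get("prostate_semi_axes", (20.0, 15.0, 15.0))),
            block_dims=tuple(p.get("block_dims", (80.0, 80.0, 80.0))),
            nodal_spacing=float(p.get("nodal_spacing", 5.0)),
            insertion_axis=tuple(p.get("insertion_axis", (0.0, 0.0, 1.0))),
            rng_seed=int(p.get("rng_seed", 0)),
            jitter=float(p.get("jitter", 0.0)))
    elif mask is None:
        raise InputError("config needs a 'phantom' or 'mask' section")

    mats_raw = raw.get("materials", {})
    materials = {
        REGION_PROSTATE: _material(mats_raw.get("prostate",
                                                {"young_kpa": 25.0, "poisson": 0.49})),
        REGION_SURROUNDING: _material(mats_raw.get("surrounding",
                                                   {"young_kpa": 10.0, "poisson": 0.49})),
    }
    ins_raw = dict(raw.get("insertion", {}))
    anchor_stiff = bool(ins_raw.pop("anchor_stiffening", True))
    insertion = InsertionConfig(**ins_raw)
    solver = SolverConfig(**raw.get("solver", {}))
    return RunConfig(phantom=phantom, mask=mask, plan=dict(raw.get("plan", {})),
                     materials=materials, insertion=insertion,
                     anchor_stiffening=anchor_stiff, solver=solver,
                     output=dict(raw.get("output", {})))


def build_domain(cfg: RunConfig):
    if cfg.phantom is not None:
        return generate_phantom(cfg.phantom)
    m = cfg.mask
    return domain_from_mask(read_mask(m["path"]), float(m.get("spacing", 5.0)),
                            margin=float(m.get("margin", 20.0)),
                            insertion_axis=tuple(m.get("insertion_axis", (0, 0, 1))))


def run_from_config(cfg: RunConfig, outdir=None, *, sequence: str | None = None,
                    anchor_stiffening: bool | None = None):
    """Run the configured procedure; returns (result, metrics dict).

    ``sequence`` and ``anchor_stiffening`` override the config (used by the
    reorder and ablation subcommands). When ``outdir`` is given, VTK series,
    the event log and a metrics JSON are written there.
    """
    domain = build_domain(cfg)
    plan = generate_needle_plan(
        domain,
        n_anchor=int(cfg.plan.get("n_anchor", 2)),
        n_catheter=int(cfg.plan.get("n_catheter", 17)),
        template_pitch=float(cfg.plan.get("template_pitch", 5.0)),
        sequence=sequence or cfg.plan.get("sequence", "alternate_lb_rt"))
    result = run_procedure(
        domain, plan, cfg.insertion, cfg.solver, materials=cfg.materials,
        anchor_stiffening=(cfg.anchor_stiffening if anchor_stiffening is None
                           else anchor_stiffening))

    vs = float(cfg.output.get("voxel_size", 1.0))
    stats = inplane_displacement_stats(result.final.u, domain)
    m0 = voxelize_region(domain, None, voxel_size=vs)
    m1 = voxelize_region(domain, result.final.u, voxel_size=vs)
    metrics = {
        "events": [s.label for s in result.snapshots],
        "n_snapshots": len(result.snapshots),
        "inplane_displacement": stats.as_dict(),
        "prostate_centroid_displacement_mm":
            [float(x) for x in prostate_centroid_displacement(result.final.u, domain)],
        "dice_initial_vs_final": dice(m0, m1),
        "errors": result.errors,
        "per_event": [
            {"event": s.label,
             "iterations": s.report.iterations if s.report else 0,
             "converged": bool(s.report.converged) if s.report else True}
            for s in result.snapshots[1:]],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .vtkio import export_procedure

        if cfg.output.get("write_vtk", True):
            export_procedure(result, outdir)
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return result, metrics
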