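"""Kinematic needle insertion: tip-following displacement, anchor and catheter
stiffening, and orchestration of the sequential multi-needle procedure.

Needles are kinematic paths, not deformable bodies. Each advance increment
moves the tip by a small distance and prescribes, on the nodes inside the
tip's influence region, an axial displacement increment weighted by distance;
dynamic relaxation then equilibrates the free nodes. The influence region is
a capsule of radius ``influence_radius`` around the trailing
``influence_radius``-long window of the penetrated path, so material moves
with the tip while it is near and is released (relaxes against the shaft) once
the tip has passed. Nodes inside the needle bore remain constrained at their
accumulated position while the needle is in place.

After both anchor needles reach depth, the surrounding (non-prostate) tissue
distal to their tip plane is stiffened ~30x, mimicking the stabilising role of
anchor needles against displacement along the insertion direction. After each
catheter reaches depth, a small tube of tissue around its path is likewise
stiffened ~30x, so previously placed catheters shield their neighbourhood from
subsequent insertions. Stiffening scales compose by maximum, never by product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import DEFAULT_MATERIALS, MaterialField
from .errors import BrachySimError, InputError
from .meshless import ShapeTable, build_shape_table
from .phantom import REGION_SURROUNDING, Domain, Needle, NeedlePlan
from .solver import (RelaxationReport, SimState, lumped_mass,
                     relax_to_equilibrium, stable_timestep)

__all__ = [
    "InsertionConfig",
    "SolverConfig",
    "Snapshot",
    "ProcedureResult",
    "tip_influence",
    "advance_needle",
    "apply_anchor_stiffening",
    "apply_catheter_stiffening",
    "run_procedure",
]


@dataclass(frozen=True)
class InsertionConfig:
    """Parameters of the kinematic insertion rule.

    influence_radius : mm, radial reach of the tip-following region (default
        3 mm ~ 4x the catheter radius).
    decay : 'linear' or 'exponential' radial decay of the displacement weight.
    increment : mm advanced per relaxation step (default 2 mm).
    stiffening_factor : multiplicative stiffening applied behind anchors and
        around placed catheters (default 30).
    catheter_stiffening_radius : mm, radius of the stiffened tube around a
        placed catheter (default 2 mm).
    """

    influence_radius: float = 3.0
    decay: str = "linear"
    increment: float = 2.0
    stiffening_factor: float = 30.0
    catheter_stiffening_radius: float = 2.0
    anchor_region_rule: str = "distal_halfspace"
    #: cap (mm) on the accumulated prescribed tip-following displacement per
    #: node: beyond it the tissue slides along the shaft instead of being
    #: dragged further. Uncapped drag accumulates to ~2 R_inf, which crushes
    #: the cells ahead of the tip; the cap also keeps the prescribed field
    #: resolvable on grids down to ~3 mm spacing.
    max_drag: float = 2.0

    def __post_init__(self):
        if self.increment <= 0:
            raise InputError("advance increment must be positive")
        if self.stiffening_factor < 1.0:
            raise InputError("stiffening factor must be >= 1")
        if self.decay not in ("linear", "exponential"):
            raise InputError(f"unknown decay rule {self.decay!r}")
        if self.anchor_region_rule != "distal_halfspace":
            raise InputError(f"unknown anchor region rule {self.anchor_region_rule!r}")

    def validate_against(self, needle: Needle) -> None:
        if self.influence_radius <= needle.radius:
            raise InputError("influence radius must exceed the needle radius")


@dataclass(frozen=True)
class SolverConfig:
    """Discretisation and relaxation parameters for the explicit solver."""

    dilation: float = 2.0
    safety: float = 0.5
    relax_tol: float = 1e-3  # mm, max displacement increment per window
    max_iter: int = 3000
    window: int = 50
    mass_scaling: bool = True
    alpha: float | None = None  # None -> adaptive (Rayleigh-estimated) damping
    ramp_steps: int = 50  # prescribed-motion ramp per advance increment
    #: mid-needle increments relax to intermediate_tol_factor * relax_tol;
    #: the final increment of every needle relaxes to relax_tol
    intermediate_tol_factor: float = 2.5


def _dist_to_segment(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment [p0, p1]."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0.0:
        return np.linalg.norm(points - p0, axis=1)
    s = np.clip((points - p0) @ d / L2, 0.0, 1.0)
    proj = p0 + s[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def tip_influence(points, needle: Needle, tip_depth: float,
                  cfg: InsertionConfig) -> np.ndarray:
    """Displacement weight w in [0, 1] of the tip-following region.

    ``r`` is the distance from each (reference-configuration) point to the tip
    window: the trailing segment of the penetrated path of length
    ``influence_radius`` ending at the current tip. w = 1 for r <= needle
    radius, decays to 0 at r = influence_radius (linear or exponential), and is
    0 beyond — in particular for points distal to the tip or proximal of the
    tip window by more than the influence radius.
    """
    cfg.validate_against(needle)
    if not 0.0 <= tip_depth <= needle.insertion_depth + 1e-9:
        raise InputError("tip depth must lie within [0, insertion_depth]")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    R = cfg.influence_radius
    a = needle.radius
    win_start = needle.tip(max(0.0, tip_depth - R))
    tip = needle.tip(tip_depth)
    r = _dist_to_segment(pts, win_start, tip)
    if cfg.decay == "linear":
        w = (R - r) / (R - a)
    else:
        k = 3.0
        w = (np.exp(-k * (r - a) / (R - a)) - np.exp(-k)) / (1.0 - np.exp(-k))
    w = np.clip(w, 0.0, 1.0)
    w[r > R] = 0.0
    return w if np.asarray(points).ndim == 2 else float(w[0])


def bore_nodes(domain: Domain, needle: Needle, tip_depth: float) -> np.ndarray:
    """Reference-configuration nodes inside the needle bore up to ``tip_depth``."""
    r = _dist_to_segment(domain.node_coords, needle.entry, needle.tip(tip_depth))
    return np.flatnonzero(r <= needle.radius)


@dataclass
class _SolverContext:
    """Bundles the discrete operators an insertion event needs."""

    domain: Domain
    shape_table: ShapeTable
    material_field: MaterialField
    solver: SolverConfig
    masses: np.ndarray = None
    dt: float = None
    correction: object = None

    def refresh(self):
        """Recompute masses and time step (call after the material field changes)."""
        self.masses = lumped_mass(self.domain, self.shape_table, self.material_field,
                                  scaled=self.solver.mass_scaling)
        self.dt = stable_timestep(self.domain, self.material_field,
                                  safety=self.solver.safety,
                                  mass_scaled=self.solver.mass_scaling)
        return self


def advance_needle(state: SimState, needle: Needle, tip_depth: float, dd: float,
                   cfg: InsertionConfig, ctx: _SolverContext,
                   bore: dict, drag: dict | None = None,
                   event: str | None = None, tol: float | None = None):
    """Advance one needle by up to ``dd`` mm and relax to equilibrium.

    Nodes with positive tip influence receive a prescribed displacement
    increment ``w * dd * direction`` composed with their current displacement;
    after relaxation the prescribed set is released except nodes inside the
    bore of any placed needle (tracked in ``bore``: node index -> held
    displacement), which stay constrained while the needles are in place.
    ``drag`` accumulates each node's total prescribed tip-following motion so
    it can be capped at ``cfg.max_drag`` (mm).

    Returns ``(state, report, new_tip_depth)``.
    """
    dd_eff = min(dd, needle.insertion_depth - tip_depth)
    if dd_eff <= 0.0:
        return state, RelaxationReport(0, 0.0, 0.0, True), tip_depth
    if drag is None:
        drag = {}
    cap = cfg.max_drag
    new_depth = tip_depth + dd_eff
    w = tip_influence(ctx.domain.node_coords, needle, new_depth, cfg)
    w[state.fixed] = 0.0
    moved = np.flatnonzero(w > 0.0)
    targets = {}
    for i in moved:
        i = int(i)
        du = min(w[i] * dd_eff, max(0.0, cap - drag.get(i, 0.0)))
        if du <= 0.0:
            continue
        drag[i] = drag.get(i, 0.0) + du
        targets[i] = state.u[i] + du * needle.axis
    # held bore nodes of earlier needles keep their position unless the tip
    # region claims them for this advance
    merged = {**{i: t.copy() for i, t in bore.items()}, **targets}
    idx = np.fromiter(merged.keys(), dtype=np.int64)
    state.set_prescribed(idx, np.array([merged[i] for i in idx]))
    state, report = relax_to_equilibrium(
        state, ctx.shape_table, ctx.material_field, ctx.domain,
        tol=(ctx.solver.relax_tol if tol is None else tol),
        max_iter=ctx.solver.max_iter,
        window=ctx.solver.window, dt=ctx.dt, alpha=ctx.solver.alpha,
        safety=ctx.solver.safety, mass_scaling=ctx.solver.mass_scaling,
        masses=ctx.masses, correction=ctx.correction,
        ramp_steps=ctx.solver.ramp_steps, event=event)
    # update the persistent bore set for this needle at its current depth
    for i in bore_nodes(ctx.domain, needle, new_depth):
        if int(i) not in np.asarray(state.fixed):
            bore[int(i)] = state.u[i].copy()
    idx = np.fromiter(bore.keys(), dtype=np.int64) if bore else np.empty(0, np.int64)
    state.clear_prescribed()
    if idx.size:
        state.set_prescribed(idx, np.array([bore[int(i)] for i in idx]))
    return state, report, new_depth


def apply_anchor_stiffening(field_: MaterialField, anchors, domain: Domain,
                            cfg: InsertionConfig) -> MaterialField:
    """Stiffen surrounding tissue distal to the anchors' tip plane.

    Integration points labelled surrounding whose axial coordinate (along the
    insertion axis) lies beyond the shallowest anchor tip get
    s <- max(s, stiffening_factor); prostate points are never modified.
    """
    if not anchors:
        return field_
    axis = domain.insertion_axis
    tip_w = min(float(n.tip() @ axis) for n in anchors)
    w_ip = domain.ip_coords @ axis
    sel = np.flatnonzero((w_ip > tip_w) & (domain.ip_region == REGION_SURROUNDING))
    w_nd = domain.node_coords @ axis
    sel_n = np.flatnonzero((w_nd > tip_w) & (domain.node_region == REGION_SURROUNDING))
    field_.stiffen(sel, cfg.stiffening_factor, node_indices=sel_n)
    return field_


def apply_catheter_stiffening(field_: MaterialField, placed: Needle, domain: Domain,
                              cfg: InsertionConfig) -> MaterialField:
    """Stiffen the tube of tissue around a fully placed catheter path."""
    r = _dist_to_segment(domain.ip_coords, placed.entry, placed.tip())
    sel = np.flatnonzero(r <= cfg.catheter_stiffening_radius)
    r_n = _dist_to_segment(domain.node_coords, placed.entry, placed.tip())
    sel_n = np.flatnonzero(r_n <= cfg.catheter_stiffening_radius)
    field_.stiffen(sel, cfg.stiffening_factor, node_indices=sel_n)
    return field_


@dataclass
class Snapshot:
    """State after one insertion event (or the initial state)."""

    label: str
    u: np.ndarray
    report: RelaxationReport | None = None


@dataclass
class ProcedureResult:
    """Ordered snapshots of the procedure plus the final material field."""

    snapshots: list
    material_field: MaterialField
    domain: Domain
    plan: NeedlePlan | None = None
    errors: list = field(default_factory=list)

    def labels(self):
        return [s.label for s in self.snapshots]

    def snapshot(self, label: str) -> Snapshot:
        for s in self.snapshots:
            if s.label == label:
                return s
        raise KeyError(f"no snapshot for event {label!r}; have {self.labels()}")

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def run_procedure(domain: Domain, plan: NeedlePlan, cfg: InsertionConfig | None = None,
                  solver: SolverConfig | None = None, *,
                  materials: dict | None = None,
                  anchor_stiffening: bool = True,
                  shape_table: ShapeTable | None = None,
                  progress=None) -> ProcedureResult:
    """Run the full sequential insertion procedure.

    Each needle in plan order is advanced in ``cfg.increment`` steps to full
    depth, relaxing after every increment. After the last anchor the anchor
    stiffening is applied (unless ``anchor_stiffening`` is False — the
    ablation scenario); after each catheter reaches depth the catheter
    stiffening is applied. A snapshot is stored per event, plus the initial
    state. On an unrecoverable numerical error a partial result is returned
    with the error recorded in ``result.errors``.
    """
    cfg = cfg or InsertionConfig()
    solver = solver or SolverConfig()
    for n in plan:
        cfg.validate_against(n)
    if shape_table is None:
        shape_table = build_shape_table(domain, dilation=solver.dilation)
    mats = {k: v for k, v in (materials or DEFAULT_MATERIALS).items()}
    field_ = MaterialField.from_domain(domain, mats)
    ctx = _SolverContext(domain, shape_table, field_, solver).refresh()

    state = SimState.zeros(domain.n_nodes, fixed=domain.boundary_sets["fixed_external"])
    snapshots = [Snapshot("initial", state.u.copy())]
    errors = []
    bore: dict = {}
    drag: dict = {}
    anchors_done = []
    n_anchor_total = len(plan.anchors())
    counters = {"anchor": 0, "catheter": 0}

    for needle in plan:
        counters[needle.kind] += 1
        label = f"{needle.kind}_{counters[needle.kind]}"
        depth = 0.0
        agg_iters, agg_conv, last_report = 0, True, None
        try:
            while depth < needle.insertion_depth - 1e-9:
                final = depth + cfg.increment >= needle.insertion_depth - 1e-9
                tol = (solver.relax_tol if final
                       else solver.relax_tol * solver.intermediate_tol_factor)
                state, report, depth = advance_needle(
                    state, needle, depth, cfg.increment, cfg, ctx, bore,
                    drag=drag, event=label, tol=tol)
                agg_iters += report.iterations
                agg_conv = agg_conv and report.converged
                last_report = report
        except BrachySimError as e:
            errors.append(f"{label}: {e}")
            snapshots.append(Snapshot(label, state.u.copy(), last_report))
            break
        if needle.kind == "anchor":
            anchors_done.append(needle)
            if len(anchors_done) == n_anchor_total and anchor_stiffening:
                apply_anchor_stiffening(field_, anchors_done, domain, cfg)
                ctx.refresh()
        else:
            apply_catheter_stiffening(field_, needle, domain, cfg)
            ctx.refresh()
        snapshots.append(Snapshot(
            label, state.u.copy(),
            RelaxationReport(agg_iters,
                             last_report.kinetic_energy if last_report else 0.0,
                             last_report.displacement_increment if last_report else 0.0,
                             agg_conv)))
        if progress is not None:
            progress(label, snapshots[-1])
    return ProcedureResult(snapshots=snapshots, material_field=field_,
                           domain=domain, plan=plan, errors=errors)
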