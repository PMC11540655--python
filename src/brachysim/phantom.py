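"""Synthetic prostate phantoms, needle plans and mask-derived domains.

The phantom stands in for a patient-specific computational grid: an ellipsoidal
prostate (default ~40 mm span) embedded in a softer cuboid block of surrounding
tissue, discretised as a regular node lattice with one integration point per
background cell. Needle plans emulate a transperineal brachytherapy template:
two thin anchor needles near the gland midline followed by catheter-needles on
a square template grid covering the prostate silhouette, inserted in a
configurable alternating order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CapacityError, GeometryError, InputError, ResolutionError
from .masks import VoxelMask

__all__ = [
    "REGION_SURROUNDING",
    "REGION_PROSTATE",
    "PhantomSpec",
    "Domain",
    "Needle",
    "NeedlePlan",
    "generate_phantom",
    "box_domain",
    "generate_needle_plan",
    "domain_from_mask",
]

REGION_SURROUNDING = 0
REGION_PROSTATE = 1

ANCHOR_RADIUS = 0.5  # mm (1 mm diameter anchor needles)
CATHETER_RADIUS = 0.75  # mm (1.5 mm diameter catheter-needles)
#: anchors stop at this fraction of the prostate extent along the insertion axis
ANCHOR_DEPTH_FRACTION = 2.0 / 3.0
#: catheters overshoot the distal prostate boundary by this margin (mm)
CATHETER_OVERSHOOT = 2.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n == 0:
        raise InputError("zero-length axis vector")
    return v / n


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic prostate-in-block phantom.

    Parameters
    ----------
    prostate_semi_axes : (a, b, c) mm
        Ellipsoid semi-axes, aligned with the coordinate axes.
    block_dims : (Lx, Ly, Lz) mm
        Extent of the surrounding tissue block.
    nodal_spacing : float, mm
        Lattice spacing; must resolve the smallest semi-axis with >= 3 nodes.
    insertion_axis : unit vector
        Axis along which needles travel; must be grid aligned (+-x, +-y, +-z).
    rng_seed : int
        Seed for the (optional) interior-node jitter.
    jitter : float
        Interior nodes are perturbed uniformly by up to ``jitter * spacing``
        per component; 0 gives a perfectly regular lattice.
    """

    prostate_semi_axes: tuple = (20.0, 15.0, 15.0)
    block_dims: tuple = (80.0, 80.0, 80.0)
    nodal_spacing: float = 5.0
    insertion_axis: tuple = (0.0, 0.0, 1.0)
    rng_seed: int = 0
    jitter: float = 0.0
    quadrature: str = "cell"

    def __post_init__(self):
        axes = np.asarray(self.prostate_semi_axes, dtype=float)
        dims = np.asarray(self.block_dims, dtype=float)
        if axes.shape != (3,) or np.any(axes <= 0):
            raise GeometryError("prostate semi-axes must be three positive lengths")
        if dims.shape != (3,) or np.any(dims <= 0):
            raise GeometryError("block dimensions must be three positive lengths")
        if np.any(2 * axes >= dims):
            raise GeometryError("prostate ellipsoid must fit strictly inside the block")
        h = float(self.nodal_spacing)
        if h <= 0:
            raise ResolutionError("nodal spacing must be positive")
        if h > axes.min() / 3.0:
            raise ResolutionError(
                f"nodal spacing {h} mm too coarse: must be <= min semi-axis / 3 "
                f"= {axes.min() / 3.0:.3g} mm"
            )
        ax = _unit(self.insertion_axis)
        if not np.isclose(np.abs(ax).max(), 1.0, atol=1e-9):
            raise GeometryError("insertion axis must be aligned with a grid axis")
        if not (0.0 <= float(self.jitter) < 0.5):
            raise InputError("jitter must lie in [0, 0.5)")


@dataclass
class Domain:
    """Reference-configuration point cloud with background-cell quadrature.

    Coordinates are in mm. ``ip_weights`` are cell volumes (mm^3) so that the
    sum of weights equals the meshed volume exactly. ``boundary_sets`` holds
    disjoint node-index sets ``fixed_external`` (clamped outer boundary) and
    ``insertion_face`` (traction-free face pierced by the needles).
    """

    node_coords: np.ndarray
    ip_coords: np.ndarray
    ip_weights: np.ndarray
    node_region: np.ndarray
    ip_region: np.ndarray
    boundary_sets: dict
    nodal_spacing: float
    insertion_axis: np.ndarray
    prostate_center: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_ips(self) -> int:
        return self.ip_coords.shape[0]

    def prostate_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.node_region == REGION_PROSTATE)

    def region_volume(self, region: int) -> float:
        """Quadrature volume (mm^3) of a region."""
        return float(self.ip_weights[self.ip_region == region].sum())

    def validate(self) -> None:
        if np.any(self.ip_weights <= 0):
            raise GeometryError("quadrature weights must be positive")
        fx = set(self.boundary_sets["fixed_external"].tolist())
        fi = set(self.boundary_sets["insertion_face"].tolist())
        if fx & fi:
            raise GeometryError("fixed_external and insertion_face must be disjoint")


def _lattice(extent_lo, extent_hi, h):
    """1D lattice coordinates covering [lo, hi] at spacing h (from lo)."""
    n = int(np.floor((extent_hi - extent_lo) / h + 1e-9)) + 1
    return extent_lo + np.arange(n) * h


#: quadrature schemes: one cell-centre point, or full 2x2x2 Gauss per cell
QUADRATURES = ("cell", "gauss2")


def _build_lattice_domain(origin, dims, h, axis, label_fn, seed=0, jitter=0.0,
                          prostate_center=None, quadrature="cell"):
    origin = np.asarray(origin, dtype=float)
    dims = np.asarray(dims, dtype=float)
    xs = [_lattice(origin[k], origin[k] + dims[k], h) for k in range(3)]
    counts = [len(x) for x in xs]
    if min(counts) < 3:
        raise ResolutionError("lattice needs at least 3 nodes per axis")
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    lo = origin
    hi = np.array([x[-1] for x in xs])
    on_face = np.stack([np.isclose(nodes[:, k], lo[k]) | np.isclose(nodes[:, k], hi[k])
                        for k in range(3)], axis=1)

    if jitter > 0:
        rng = np.random.default_rng(seed)
        interior = ~on_face.any(axis=1)
        nodes = nodes.copy()
        nodes[interior] += rng.uniform(-jitter * h, jitter * h, size=(interior.sum(), 3))

    # background-cell quadrature: cell centres, or 2x2x2 Gauss points. The
    # single-point scheme is cheap but leaves a near-zero-energy (hourglass)
    # null space — there are fewer cells than nodes — so verification-grade
    # statics should use 'gauss2'.
    if quadrature not in QUADRATURES:
        raise InputError(f"unknown quadrature {quadrature!r}; choose from {QUADRATURES}")
    cs = [x[:-1] + h / 2 for x in xs]
    CX, CY, CZ = np.meshgrid(*cs, indexing="ij")
    centers = np.column_stack([CX.ravel(), CY.ravel(), CZ.ravel()])
    if quadrature == "cell":
        ips = centers
        weights = np.full(ips.shape[0], h**3)
    else:
        g = h / (2.0 * np.sqrt(3.0))
        offs = np.array([[sx * g, sy * g, sz * g]
                         for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        ips = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        weights = np.full(ips.shape[0], h**3 / 8.0)

    node_region = label_fn(nodes).astype(np.int8)
    ip_region = label_fn(ips).astype(np.int8)

    # entry face: outward normal is -axis (needles travel along +axis)
    k = int(np.argmax(np.abs(axis)))
    entry_lo = axis[k] > 0
    on_entry = np.isclose(nodes[:, k], lo[k]) if entry_lo else np.isclose(nodes[:, k], hi[k])
    n_faces = on_face.sum(axis=1)
    insertion_face = np.flatnonzero(on_entry & (n_faces == 1))
    fixed_external = np.flatnonzero(on_face.any(axis=1) & ~(on_entry & (n_faces == 1)))

    dom = Domain(
        node_coords=nodes,
        ip_coords=ips,
        ip_weights=weights,
        node_region=node_region,
        ip_region=ip_region,
        boundary_sets={"fixed_external": fixed_external, "insertion_face": insertion_face},
        nodal_spacing=float(h),
        insertion_axis=np.asarray(axis, dtype=float),
        prostate_center=np.asarray(
            prostate_center if prostate_center is not None else (lo + hi) / 2, dtype=float),
    )
    dom.validate()
    return dom


def generate_phantom(spec: PhantomSpec) -> Domain:
    """Generate the synthetic prostate-in-block domain described by ``spec``.

    Nodes form a regular lattice at ``spec.nodal_spacing`` filling the block;
    nodes (and cell-centre integration points) inside the centred ellipsoid are
    labelled prostate. All block faces are clamped except the face pierced by
    the insertion axis, which is traction free (its rim stays clamped).
    """
    axes = np.asarray(spec.prostate_semi_axes, dtype=float)
    dims = np.asarray(spec.block_dims, dtype=float)
    h = float(spec.nodal_spacing)
    axis = _unit(spec.insertion_axis)

    # centre the ellipsoid in the meshed extent (which may be < block_dims when
    # the spacing does not divide the block evenly)
    meshed = np.array([(int(np.floor(d / h + 1e-9))) * h for d in dims])
    center = meshed / 2
    if np.any(center - axes <= 0) or np.any(center + axes >= meshed):
        raise GeometryError("prostate ellipsoid does not fit inside the meshed block")

    def label(pts):
        q = ((pts - center) / axes) ** 2
        return (q.sum(axis=1) <= 1.0).astype(np.int8) * REGION_PROSTATE

    dom = _build_lattice_domain(np.zeros(3), dims, h, axis, label,
                                seed=spec.rng_seed, jitter=spec.jitter,
                                prostate_center=center,
                                quadrature=spec.quadrature)
    if (dom.node_region == REGION_PROSTATE).sum() == 0:
        raise ResolutionError("no prostate nodes at this spacing")
    return dom


def box_domain(dims, spacing, region: int = REGION_SURROUNDING,
               quadrature: str = "gauss2") -> Domain:
    """Homogeneous rectangular block (verification geometries: bars, patch tests).

    Defaults to full 2x2x2 Gauss quadrature, which suppresses the hourglass
    modes of single-point integration and is affordable at verification sizes.
    """

    def label(pts):
        return np.full(pts.shape[0], region, dtype=np.int8)

    return _build_lattice_domain(np.zeros(3), np.asarray(dims, float), float(spacing),
                                 np.array([0.0, 0.0, 1.0]), label,
                                 quadrature=quadrature)


@dataclass(frozen=True)
class Needle:
    """A single insertion event: straight needle advanced along ``direction``."""

    entry_point: tuple
    direction: tuple
    insertion_depth: float
    radius: float
    kind: str  # 'anchor' | 'catheter'
    order_index: int

    def __post_init__(self):
        if self.radius <= 0:
            raise InputError("needle radius must be positive")
        if self.insertion_depth <= 0:
            raise InputError("insertion depth must be positive")
        if self.kind not in ("anchor", "catheter"):
            raise InputError(f"unknown needle kind {self.kind!r}")

    @property
    def entry(self) -> np.ndarray:
        return np.asarray(self.entry_point, dtype=float)

    @property
    def axis(self) -> np.ndarray:
        return _unit(self.direction)

    def tip(self, depth=None) -> np.ndarray:
        d = self.insertion_depth if depth is None else depth
        return self.entry + d * self.axis


@dataclass
class NeedlePlan:
    """Ordered list of needles; iteration follows ``order_index``."""

    needles: list

    def __post_init__(self):
        self.needles = sorted(self.needles, key=lambda n: n.order_index)
        idx = [n.order_index for n in self.needles]
        if idx != list(range(len(idx))):
            raise InputError("order_index must be a permutation of 0..n-1")

    def __len__(self):
        return len(self.needles)

    def __iter__(self):
        return iter(self.needles)

    def anchors(self):
        return [n for n in self.needles if n.kind == "anchor"]

    def catheters(self):
        return [n for n in self.needles if n.kind == "catheter"]


def _face_frame(axis):
    """In-plane axes (u, v) spanning the insertion face, right-handed with axis."""
    k = int(np.argmax(np.abs(axis)))
    u, v = (k + 1) % 3, (k + 2) % 3
    return k, u, v


def _order_alternating(holes, score_a, score_b):
    """Alternately pick extreme holes by two scores; returns index permutation."""
    remaining = list(range(len(holes)))
    order = []
    pick_a = True
    while remaining:
        if pick_a:
            j = min(remaining, key=lambda i: (score_a(holes[i]), holes[i][0], holes[i][1]))
        else:
            j = max(remaining, key=lambda i: (score_b(holes[i]), -holes[i][0], -holes[i][1]))
        order.append(j)
        remaining.remove(j)
        pick_a = not pick_a
    return order


ORDERING_RULES = ("alternate_lb_rt", "alternate_rb_lb")


def generate_needle_plan(domain: Domain, n_anchor: int = 2, n_catheter: int = 17,
                         template_pitch: float = 5.0,
                         sequence: str = "alternate_lb_rt") -> NeedlePlan:
    """Place needles on a transperineal template grid over the prostate silhouette.

    Anchors (radius 0.5 mm) take the template holes nearest the gland centre and
    stop at two thirds of the prostate extent along the insertion axis;
    catheters (radius 0.75 mm) take the nearest remaining holes and traverse to
    the distal prostate boundary plus 2 mm. Two built-in orderings mimic
    alternating clinical sequences: ``alternate_lb_rt`` (left-bottom then
    right-top, working inward) and ``alternate_rb_lb`` (bottom-right then
    bottom-left).
    """
    if sequence not in ORDERING_RULES:
        raise InputError(f"unknown ordering rule {sequence!r}; choose from {ORDERING_RULES}")
    if template_pitch <= 0:
        raise InputError("template pitch must be positive")
    axis = _unit(domain.insertion_axis)
    k, ui, vi = _face_frame(axis)
    center = domain.prostate_center

    pts = domain.node_coords[domain.prostate_nodes()]
    if pts.shape[0] == 0:
        raise InputError("domain has no prostate region")
    # silhouette half-extents in the face plane
    a_u = float(np.abs(pts[:, ui] - center[ui]).max()) + 1e-9
    a_v = float(np.abs(pts[:, vi] - center[vi]).max()) + 1e-9

    K_u = int(np.floor(a_u / template_pitch))
    K_v = int(np.floor(a_v / template_pitch))
    holes = []
    for i in range(-K_u, K_u + 1):
        for j in range(-K_v, K_v + 1):
            du, dv = i * template_pitch, j * template_pitch
            if (du / a_u) ** 2 + (dv / a_v) ** 2 <= 1.0:
                holes.append((du, dv))
    if len(holes) < n_anchor + n_catheter:
        raise CapacityError(
            f"{n_anchor + n_catheter} needles requested but only {len(holes)} "
            f"template holes cover the prostate silhouette")

    holes.sort(key=lambda h: (h[0] ** 2 + h[1] ** 2, h[0], h[1]))
    anchor_holes = holes[:n_anchor]
    cath_holes = holes[n_anchor:n_anchor + n_catheter]

    # axial geometry: entry face -> prostate extent along the axis
    w_entry = 0.0 if axis[k] > 0 else domain.node_coords[:, k].max()
    sgn = 1.0 if axis[k] > 0 else -1.0
    w_lo = sgn * (pts[:, k].min() - w_entry) if sgn > 0 else (w_entry - pts[:, k].max())
    w_hi = sgn * (pts[:, k].max() - w_entry) if sgn > 0 else (w_entry - pts[:, k].min())
    anchor_depth = w_lo + ANCHOR_DEPTH_FRACTION * (w_hi - w_lo)
    catheter_depth = w_hi + CATHETER_OVERSHOOT

    def entry(hole):
        p = np.zeros(3)
        p[k] = w_entry
        p[ui] = center[ui] + hole[0]
        p[vi] = center[vi] + hole[1]
        return tuple(float(v) for v in p)

    needles = []
    for m, hole in enumerate(sorted(anchor_holes)):
        needles.append(Needle(entry(hole), tuple(axis), anchor_depth,
                              ANCHOR_RADIUS, "anchor", m))
    if sequence == "alternate_lb_rt":
        perm = _order_alternating(cath_holes,
                                  score_a=lambda h: h[0] + h[1],
                                  score_b=lambda h: h[0] + h[1])
    else:  # alternate_rb_lb
        perm = _order_alternating(cath_holes,
                                  score_a=lambda h: -(h[0] - h[1]),
                                  score_b=lambda h: -(h[0] + h[1]))
    for m, j in enumerate(perm):
        needles.append(Needle(entry(cath_holes[j]), tuple(axis), catheter_depth,
                              CATHETER_RADIUS, "catheter", n_anchor + m))
    return NeedlePlan(needles)


def domain_from_mask(mask: VoxelMask, spacing: float, margin: float = 20.0,
                     insertion_axis=(0.0, 0.0, 1.0)) -> Domain:
    """Build a simulation domain from a binary prostate segmentation.

    Nodes form a lattice at ``spacing`` covering the mask bounding box plus a
    ``margin`` shell of surrounding tissue; nodes whose nearest voxel is
    foreground are labelled prostate. Boundary sets follow the same convention
    as :func:`generate_phantom`.
    """
    if not mask.data.any():
        raise InputError("mask is empty (all zero)")
    if spacing <= 0:
        raise ResolutionError("spacing must be positive")
    axis = _unit(insertion_axis)
    fg = mask.voxel_centers()
    lo = fg.min(axis=0) - margin
    hi = fg.max(axis=0) + margin

    def label(ptset):
        idx = np.round((ptset - mask.origin) / mask.voxel_size).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
        out = np.zeros(ptset.shape[0], dtype=np.int8)
        sel = idx[ok]
        out[ok] = mask.data[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out * REGION_PROSTATE

    dom = _build_lattice_domain(lo, hi - lo, float(spacing), axis, label,
                                prostate_center=fg.mean(axis=0))
    if (dom.node_region == REGION_PROSTATE).sum() == 0:
        raise ResolutionError("spacing too coarse: no lattice node falls inside the mask")
    return dom
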