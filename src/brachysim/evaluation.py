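"""Quantitative evaluation: voxelisation, Dice overlap, displacement statistics.

The deformed prostate is voxelised onto an axis-aligned grid by reconstructing
a closed surface from the deformed prostate nodes (alpha-shape over their
Delaunay tessellation, convex-hull fallback for near-convex clouds) and
marking voxels whose centres fall inside; the mask is then dilated by half the
nodal spacing to compensate the half-cell inset of the outermost lattice nodes
relative to the continuum boundary. Dice coefficients are always computed on a
common cubic domain: the union bounding box of the two masks inflated to a
cube, at the finest of the two voxel sizes, with nearest-neighbour resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import GeometryError
from .insertion import ProcedureResult
from .masks import VoxelMask
from .phantom import REGION_PROSTATE, Domain

__all__ = [
    "DisplacementStats",
    "voxelize_region",
    "dice",
    "inplane_displacement_stats",
    "compare_snapshots",
    "prostate_centroid_displacement",
]


@dataclass
class DisplacementStats:
    """Mean/SD/max of in-plane displacement magnitudes (mm)."""

    mean: float
    sd: float
    max: float
    plane_normal: tuple

    def as_dict(self) -> dict:
        return {"mean_mm": self.mean, "sd_mm": self.sd, "max_mm": self.max,
                "plane_normal": list(self.plane_normal)}


def _tet_circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron; degenerate (flat) tets get inf."""
    a = points[simplices[:, 0]]
    rows = np.stack([points[simplices[:, k]] - a for k in (1, 2, 3)], axis=1)  # (m,3,3)
    sq = np.einsum("mij,mij->mi", rows, rows)  # squared edge lengths from a
    det = np.linalg.det(rows)
    scale = np.abs(rows).max(axis=(1, 2)) ** 3 + 1e-300
    ok = np.abs(det) > 1e-9 * scale
    r = np.full(simplices.shape[0], np.inf)
    if ok.any():
        # circumcentre offset c solves 2 rows . c = sq
        c = np.linalg.solve(2.0 * rows[ok], sq[ok][..., None])[..., 0]
        r[ok] = np.linalg.norm(c, axis=1)
    return r


def voxelize_region(domain: Domain, state=None, region: int = REGION_PROSTATE,
                    voxel_size: float = 1.0, alpha: float | None = None,
                    dilate: float | None = None) -> VoxelMask:
    """Voxelise a (possibly deformed) region of the domain.

    Parameters
    ----------
    state : SimState or ndarray (n, 3) or None
        Nodal displacements added to the reference coordinates; None keeps the
        reference configuration.
    alpha : mm
        Alpha-shape radius; default 2x nodal spacing. If the alpha criterion
        removes every tetrahedron the convex hull is used instead
        (``mask.hull_fallback`` is set).
    dilate : mm
        Surface dilation; default half the nodal spacing.
    """
    u = getattr(state, "u", state)
    sel = domain.node_region == region
    pts = domain.node_coords[sel]
    if u is not None:
        pts = pts + np.asarray(u)[sel]
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite deformed node positions")
    if pts.shape[0] < 4:
        raise GeometryError("need at least 4 nodes to voxelise a region")
    alpha = 2.0 * domain.nodal_spacing if alpha is None else alpha
    dilate = 0.5 * domain.nodal_spacing if dilate is None else dilate

    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise GeometryError(f"degenerate point set for voxelisation: {e}") from None
    keep = _tet_circumradii(pts, tri.simplices) <= alpha
    hull_fallback = False
    if not keep.any():
        keep = np.ones(tri.simplices.shape[0], dtype=bool)
        hull_fallback = True

    vs = float(voxel_size)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    origin = lo - 2.0 * vs
    shape = np.ceil((hi - origin) / vs).astype(int) + 3
    ax = [origin[k] + np.arange(shape[k]) * vs for k in range(3)]
    CX, CY, CZ = np.meshgrid(*ax, indexing="ij")
    centers = np.column_stack([CX.ravel(), CY.ravel(), CZ.ravel()])
    simplex = tri.find_simplex(centers)
    inside = (simplex >= 0) & keep[np.clip(simplex, 0, None)]
    if dilate > 0:
        # the reconstructed surface passes through the outermost nodes, which
        # sit inside the continuum boundary by up to a cell; count voxels
        # within the tributary radius of any node as occupied too
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(centers[~inside])
        inside[~inside] = d <= dilate
    data = inside.reshape(shape)
    mask = VoxelMask(data, origin, vs)
    mask.hull_fallback = hull_fallback
    return mask


def _resample_to(mask: VoxelMask, origin, shape, vs) -> np.ndarray:
    """Nearest-neighbour resampling of ``mask`` onto the given grid."""
    # floor(x + 0.5), not np.round: the common grid sits at exact half-voxel
    # offsets and banker's rounding would alias neighbouring samples
    idx = [np.floor((origin[k] + np.arange(shape[k]) * vs - mask.origin[k])
                    / mask.voxel_size + 0.5).astype(int) for k in range(3)]
    ok = [np.clip(i, 0, mask.shape[k] - 1) for k, i in enumerate(idx)]
    out = mask.data[np.ix_(ok[0], ok[1], ok[2])].copy()
    for k in range(3):
        bad = (idx[k] < 0) | (idx[k] >= mask.shape[k])
        if bad.any():
            sl = [slice(None)] * 3
            sl[k] = bad
            out[tuple(sl)] = False
    return out


def common_cubic_grids(a: VoxelMask, b: VoxelMask):
    """Resample two masks onto their common cubic domain (finest voxel size)."""
    vs = min(a.voxel_size, b.voxel_size)
    lo_a, hi_a = a.world_bounds()
    lo_b, hi_b = b.world_bounds()
    lo = np.minimum(lo_a, lo_b)
    hi = np.maximum(hi_a, hi_b)
    side = float((hi - lo).max())
    center = (hi + lo) / 2
    lo_cube = center - side / 2
    n = int(np.ceil(side / vs + 1e-9))
    origin = lo_cube + vs / 2
    A = _resample_to(a, origin, (n, n, n), vs)
    B = _resample_to(b, origin, (n, n, n), vs)
    return A, B


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity coefficient D = 2|A n B| / (|A| + |B|) in [0, 1].

    Masks are first resampled onto a common cubic domain. Two empty masks give
    D = 1 with a warning.
    """
    A, B = common_cubic_grids(a, b)
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1")
        return 1.0
    return 2.0 * int((A & B).sum()) / (na + nb)


def inplane_displacement_stats(state, domain: Domain,
                               plane_normal=None) -> DisplacementStats:
    """Mean/SD/max in-plane displacement over prostate nodes.

    Displacements are projected onto the plane orthogonal to ``plane_normal``
    (default: the insertion axis — the short-axis ultrasound view).
    """
    n = np.asarray(plane_normal if plane_normal is not None
                   else domain.insertion_axis, dtype=float)
    nn = np.linalg.norm(n)
    if not np.isclose(nn, 1.0, atol=1e-6):
        raise GeometryError("plane normal must be a unit vector")
    u = getattr(state, "u", state)
    up = np.asarray(u)[domain.node_region == REGION_PROSTATE]
    u_in = up - np.outer(up @ n, n)
    mags = np.linalg.norm(u_in, axis=1)
    return DisplacementStats(mean=float(mags.mean()), sd=float(mags.std()),
                             max=float(mags.max()), plane_normal=tuple(n))


def prostate_centroid_displacement(state, domain: Domain) -> np.ndarray:
    """Mean displacement vector (mm) over prostate nodes."""
    u = getattr(state, "u", state)
    return np.asarray(u)[domain.node_region == REGION_PROSTATE].mean(axis=0)


def compare_snapshots(result: ProcedureResult, events, voxel_size: float = 1.0) -> float:
    """Dice overlap of the voxelised prostate at two snapshots of a procedure."""
    ea, eb = events
    a = voxelize_region(result.domain, result.snapshot(ea).u, voxel_size=voxel_size)
    b = voxelize_region(result.domain, result.snapshot(eb).u, voxel_size=voxel_size)
    return dice(a, b)
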