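"""Modified moving least squares (MMLS) shape functions on point clouds.

Shape functions use a quadratic monomial basis whose six second-order
coefficients carry a small diagonal penalty in the moment matrix, so the fit
degrades gracefully to linear MLS wherever the support cannot resolve
quadratics (the moment matrix stays invertible for coplanar or sparse
supports). The weight kernel is regularised-singular,

    w(r) = 1 / ((r/h)^2 + eps),   eps = 1e-9,

which makes the shape functions interpolating to ~1e-6 at the nodes, so
Dirichlet values can be imposed directly on nodal parameters. Values and
analytic reference-configuration gradients are tabulated sparsely at all
integration points, plus values at the nodes for the delta-property check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .errors import DiscretisationError, InputError, NumericalError
from .phantom import Domain

__all__ = [
    "N_MIN",
    "SupportTable",
    "ShapeTable",
    "find_supports",
    "build_supports",
    "mmls_shape",
    "build_shape_table",
]

#: minimum support size: quadratic basis (10 monomials) + 1
N_MIN = 11
BASIS_SIZE = 10
#: weight-kernel regularisation (in units of (r/h)^2); small enough that the
#: interpolating (delta) property holds to ~1e-6 even when a random cloud
#: contains a near-coincident node pair
EPS_W = 1e-9
#: diagonal penalty on the quadratic moment-matrix block, relative to the
#: weight sum (a translation-invariant measure of the moment-matrix scale, so
#: the shape functions stay exactly differentiable); small enough to recover
#: quadratic fields on well-populated supports
PENALTY_REL = 1e-8
#: local support enlargement per retry when |support| < N_MIN
ENLARGE = 1.25
MAX_ENLARGE = 5


@dataclass
class SupportTable:
    """Per-evaluation-point neighbour lists and support radii."""

    indices: list  # list of int arrays, one per evaluation point
    radii: np.ndarray  # support radius h per evaluation point (mm)

    def __len__(self):
        return len(self.indices)


def find_supports(eval_points: np.ndarray, node_coords: np.ndarray, h0: float,
                  n_min: int = N_MIN) -> SupportTable:
    """Radius search with bounded local enlargement until ``n_min`` is reached."""
    eval_points = np.asarray(eval_points, dtype=float)
    tree = cKDTree(node_coords)
    lists = tree.query_ball_point(eval_points, h0)
    radii = np.full(eval_points.shape[0], h0)
    indices = []
    for i, lst in enumerate(lists):
        h = h0
        tries = 0
        while len(lst) < n_min:
            tries += 1
            if tries > MAX_ENLARGE:
                raise DiscretisationError(
                    f"support of evaluation point {i} at {eval_points[i]} has only "
                    f"{len(lst)} nodes after {MAX_ENLARGE} enlargements (need {n_min})")
            h *= ENLARGE
            lst = tree.query_ball_point(eval_points[i], h)
        radii[i] = h
        indices.append(np.asarray(sorted(lst), dtype=np.int64))
    return SupportTable(indices=indices, radii=radii)


def build_supports(domain: Domain, dilation: float = 2.0,
                   n_min: int = N_MIN) -> SupportTable:
    """Supports for all integration points; base radius = dilation x spacing."""
    if dilation < 1.5:
        raise InputError("support dilation must be >= 1.5")
    return find_supports(domain.ip_coords, domain.node_coords,
                         dilation * domain.nodal_spacing, n_min)


def _basis(xi: np.ndarray) -> np.ndarray:
    """Quadratic monomials [1, x, y, z, x2, y2, z2, xy, yz, zx] of (k,3) points."""
    x, y, z = xi[:, 0], xi[:, 1], xi[:, 2]
    return np.column_stack([np.ones_like(x), x, y, z,
                            x * x, y * y, z * z, x * y, y * z, z * x])


def mmls_shape(eval_point, support_nodes, h, want_gradients: bool = True):
    """MMLS shape-function values (and gradients) at a single point.

    Parameters
    ----------
    eval_point : (3,) mm
    support_nodes : (k, 3) mm, k >= N_MIN
    h : support radius in mm (sets the weight length scale)

    Returns
    -------
    values : (k,) dimensionless, summing to 1
    gradients : (k, 3) in 1/mm, or None if not requested
    """
    x = np.asarray(eval_point, dtype=float).reshape(3)
    X = np.asarray(support_nodes, dtype=float)
    k = X.shape[0]
    if k < N_MIN:
        raise InputError(f"support has {k} nodes; need at least {N_MIN}")
    xi = (X - x) / h  # local frame centred (and scaled) at the evaluation point
    rho2 = np.einsum("ij,ij->i", xi, xi)
    w = 1.0 / (rho2 + EPS_W)
    P = _basis(xi)

    M = (P * w[:, None]).T @ P
    mu_p = PENALTY_REL * w.sum()
    M[np.arange(4, 10), np.arange(4, 10)] += mu_p

    p0 = np.zeros(BASIS_SIZE)
    p0[0] = 1.0
    try:
        gamma = np.linalg.solve(M, p0)
    except np.linalg.LinAlgError:
        raise NumericalError(
            f"singular MMLS moment matrix at {x} despite penalty "
            f"(cond ~ {np.linalg.cond(M):.2e})")
    if not np.all(np.isfinite(gamma)):
        raise NumericalError(f"non-finite MMLS solve at {x} (cond ~ {np.linalg.cond(M):.2e})")

    pg = P @ gamma
    phi = w * pg
    if not want_gradients:
        return phi, None

    # analytic gradients in a frame whose origin is held fixed at eval_point:
    #   dphi_i = dw_i (p_i . gamma) + w_i (p_i . dgamma)
    #   dgamma_b = M^-1 (dp0_b - dM_b gamma)
    # dM_b includes the weight-sum penalty's variation; dp0 has only the
    # linear rows. dw_i/dy = 2 xi_i / (h (rho^2 + eps)^2).
    dw = 2.0 * xi * (1.0 / (rho2 + EPS_W) ** 2)[:, None] / h  # (k,3)
    grad = np.empty((k, 3))
    for b in range(3):
        rhs = -(P.T @ (dw[:, b] * pg))  # -dM_b gamma, dM_b = sum dw p p^T
        rhs[1 + b] += 1.0 / h  # dp0/dy_b
        rhs[4:10] -= PENALTY_REL * dw[:, b].sum() * gamma[4:10]
        dgamma = np.linalg.solve(M, rhs)
        grad[:, b] = dw[:, b] * pg + w * (P @ dgamma)
    return phi, grad


@dataclass
class ShapeTable:
    """Sparse shape-function tabulation over a domain.

    ``phi`` and ``grad[b]`` are CSR matrices of shape (n_ips, n_nodes) holding
    values and reference gradients at the integration points; ``phi_nodes``
    and ``grad_nodes`` hold the same quantities evaluated at the nodes
    (n_nodes, n_nodes). ``discrete_div`` is the quadrature divergence
    s_i = sum_ip w_ip grad0 phi_i, the discrete counterpart of the boundary
    flux of phi_i; it vanishes for nodes deep in a symmetric lattice and
    drives the Dirichlet reaction correction in the solver.
    """

    phi: sp.csr_matrix
    grad: tuple  # (Gx, Gy, Gz), each (n_ips, n_nodes) CSR in 1/mm
    phi_nodes: sp.csr_matrix
    grad_nodes: tuple
    discrete_div: np.ndarray  # (n_nodes, 3), mm^2
    supports: SupportTable

    def grad_csr_arrays(self):
        """Aligned CSR arrays (indptr, indices, gx, gy, gz) for fused assembly.

        The three gradient matrices share one sparsity pattern by
        construction, so a single indptr/indices pair describes all of them.
        """
        Gx, Gy, Gz = self.grad
        return Gx.indptr, Gx.indices, Gx.data, Gy.data, Gz.data

    @property
    def n_ips(self):
        return self.phi.shape[0]

    @property
    def n_nodes(self):
        return self.phi.shape[1]


def _tabulate(eval_points, node_coords, supports, want_gradients):
    rows, cols, vals = [], [], []
    gvals = [[], [], []] if want_gradients else None
    for i, idx in enumerate(supports.indices):
        phi, grad = mmls_shape(eval_points[i], node_coords[idx], supports.radii[i],
                               want_gradients=want_gradients)
        rows.append(np.full(len(idx), i, dtype=np.int64))
        cols.append(idx)
        vals.append(phi)
        if want_gradients:
            for b in range(3):
                gvals[b].append(grad[:, b])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    shape = (len(supports), node_coords.shape[0])
    phi = sp.csr_matrix((np.concatenate(vals), (rows, cols)), shape=shape)
    if not want_gradients:
        return phi, None
    G = tuple(sp.csr_matrix((np.concatenate(gvals[b]), (rows, cols)), shape=shape)
              for b in range(3))
    return phi, G


def domain_hash(domain: Domain) -> str:
    """Content hash of a domain's geometry (for shape-table caching)."""
    import hashlib

    h = hashlib.sha256()
    for arr in (domain.node_coords, domain.ip_coords, domain.ip_weights):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def save_shape_table(path, table: ShapeTable, domain: Domain) -> None:
    """Cache a shape table to HDF5, keyed by the domain content hash."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["domain_hash"] = domain_hash(domain)
        for name, mat in (("phi", table.phi), ("phi_nodes", table.phi_nodes),
                          ("gx", table.grad[0]), ("gy", table.grad[1]),
                          ("gz", table.grad[2]), ("ngx", table.grad_nodes[0]),
                          ("ngy", table.grad_nodes[1]), ("ngz", table.grad_nodes[2])):
            g = f.create_group(name)
            g.create_dataset("data", data=mat.data)
            g.create_dataset("indices", data=mat.indices)
            g.create_dataset("indptr", data=mat.indptr)
            g.attrs["shape"] = mat.shape
        f.create_dataset("discrete_div", data=table.discrete_div)


def load_shape_table(path, domain: Domain) -> ShapeTable | None:
    """Load a cached shape table; returns None on a domain-hash mismatch."""
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("domain_hash") != domain_hash(domain):
            return None

        def csr(name):
            g = f[name]
            return sp.csr_matrix((g["data"][:], g["indices"][:], g["indptr"][:]),
                                 shape=tuple(g.attrs["shape"]))

        table = ShapeTable(
            phi=csr("phi"), grad=(csr("gx"), csr("gy"), csr("gz")),
            phi_nodes=csr("phi_nodes"),
            grad_nodes=(csr("ngx"), csr("ngy"), csr("ngz")),
            discrete_div=f["discrete_div"][:],
            supports=SupportTable(indices=[], radii=np.empty(0)))
    return table


def build_shape_table(domain: Domain, supports: SupportTable | None = None,
                      dilation: float = 2.0) -> ShapeTable:
    """Tabulate MMLS values/gradients at integration points and values at nodes."""
    if supports is None:
        supports = build_supports(domain, dilation)
    phi, G = _tabulate(domain.ip_coords, domain.node_coords, supports, True)
    node_supports = find_supports(domain.node_coords, domain.node_coords,
                                  (supports.radii.min() if len(supports) else
                                   dilation * domain.nodal_spacing))
    phi_nodes, G_nodes = _tabulate(domain.node_coords, domain.node_coords,
                                   node_supports, True)
    div = np.column_stack([np.asarray(Gb.T @ domain.ip_weights).ravel() for Gb in G])
    return ShapeTable(phi=phi, grad=G, phi_nodes=phi_nodes, grad_nodes=G_nodes,
                      discrete_div=div, supports=supports)
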