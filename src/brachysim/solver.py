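"""Total-Lagrangian explicit dynamics with dynamic relaxation.

All kinematics are referred to the reference configuration: at each
integration point the deformation gradient is assembled from the tabulated
shape-function gradients, F = I + sum_i u_i (grad0 phi_i)^T, and nodal internal
forces are f_i = sum_ip w_ip P(F) grad0 phi_i. Time integration is damped
central difference with a lumped (row-sum) mass matrix; the quasi-static
solution after each insertion increment is obtained by dynamic relaxation:
damped stepping until the displacement increment over a trailing window falls
below tolerance.

Units: displacements mm, time s, moduli kPa, density kg/m^3, masses kg,
forces mN. In these units acceleration = force/mass is directly in mm/s^2.

During relaxation the nodal masses may optionally be scaled by the local
stiffening factor ("mass scaling"); this leaves the quasi-static limit
untouched while keeping the stable time step independent of needle-induced
stiffening. It is disabled in any dynamic-accuracy context.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import HAVE_NUMBA, _internal_force_kernel, _relax_window_kernel
from .constitutive import MaterialField, pk1_stress_batch
from .errors import DiscretisationError, DivergenceError, InvertedElementError
from .meshless import ShapeTable
from .phantom import Domain

__all__ = [
    "SimState",
    "RelaxationReport",
    "ReactionCorrection",
    "dirichlet_reaction_correction",
    "internal_forces",
    "lumped_mass",
    "stable_timestep",
    "step",
    "relax_to_equilibrium",
    "total_strain_energy",
]


@dataclass
class SimState:
    """Nodal displacements/velocities plus constraint sets.

    ``fixed`` nodes are pinned at u = 0. Prescribed nodes are snapped to
    ``prescribed_target`` on the components where ``prescribed_mask`` is True
    after every step (valid because the shape functions are interpolating).
    """

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    fixed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    prescribed_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    prescribed_target: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    prescribed_mask: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=bool))

    @classmethod
    def zeros(cls, n_nodes: int, fixed=None) -> "SimState":
        return cls(u=np.zeros((n_nodes, 3)), v=np.zeros((n_nodes, 3)),
                   fixed=(np.asarray(fixed, dtype=np.int64) if fixed is not None
                          else np.empty(0, dtype=np.int64)))

    def set_prescribed(self, idx, targets, mask=None) -> None:
        idx = np.asarray(idx, dtype=np.int64)
        if np.intersect1d(idx, self.fixed).size:
            raise ValueError("prescribed and fixed node sets must be disjoint")
        self.prescribed_idx = idx
        self.prescribed_target = np.asarray(targets, dtype=float).reshape(len(idx), 3)
        self.prescribed_mask = (np.ones((len(idx), 3), dtype=bool) if mask is None
                                else np.asarray(mask, dtype=bool).reshape(len(idx), 3))
        self.enforce_constraints()

    def clear_prescribed(self) -> None:
        self.prescribed_idx = np.empty(0, dtype=np.int64)
        self.prescribed_target = np.empty((0, 3))
        self.prescribed_mask = np.empty((0, 3), dtype=bool)

    def enforce_constraints(self) -> None:
        self.u[self.fixed] = 0.0
        self.v[self.fixed] = 0.0
        if self.prescribed_idx.size:
            sub_u = self.u[self.prescribed_idx]
            sub_v = self.v[self.prescribed_idx]
            sub_u[self.prescribed_mask] = self.prescribed_target[self.prescribed_mask]
            sub_v[self.prescribed_mask] = 0.0
            self.u[self.prescribed_idx] = sub_u
            self.v[self.prescribed_idx] = sub_v

    def copy(self) -> "SimState":
        return replace(self, u=self.u.copy(), v=self.v.copy(),
                       fixed=self.fixed.copy(),
                       prescribed_idx=self.prescribed_idx.copy(),
                       prescribed_target=self.prescribed_target.copy(),
                       prescribed_mask=self.prescribed_mask.copy())


@dataclass
class RelaxationReport:
    """Convergence bookkeeping for one dynamic-relaxation phase."""

    iterations: int
    kinetic_energy: float
    displacement_increment: float
    converged: bool


def deformation_gradients(u: np.ndarray, shape_table: ShapeTable) -> np.ndarray:
    """F = I + H at every integration point, H[:, a, b] = (G_b @ u)[:, a]."""
    m = shape_table.n_ips
    F = np.empty((m, 3, 3))
    for b in range(3):
        F[:, :, b] = shape_table.grad[b] @ u
    F[:, 0, 0] += 1.0
    F[:, 1, 1] += 1.0
    F[:, 2, 2] += 1.0
    return F


def internal_forces(state: SimState, shape_table: ShapeTable,
                    material_field: MaterialField, domain: Domain,
                    event: str | None = None) -> np.ndarray:
    """Nodal internal forces (mN); zero for rigid translations.

    The equation of motion is M a = f_ext - f_int with f_int returned here.
    Uses the fused (numba) assembly kernel when available; the vectorised
    scipy-sparse path is the reference fallback.
    """
    if HAVE_NUMBA:
        indptr, indices, gx, gy, gz = shape_table.grad_csr_arrays()
        f = np.zeros((domain.n_nodes, 3))
        det_min, det_arg = _internal_force_kernel(
            indptr, indices, gx, gy, gz, domain.ip_weights,
            material_field.mu_eff, material_field.kappa_eff, state.u, f)
        if det_min <= 0.0:
            raise InvertedElementError(det_arg, det_min, event=event)
        return f
    F = deformation_gradients(state.u, shape_table)
    try:
        P = pk1_stress_batch(F, material_field.mu_eff, material_field.kappa_eff)
    except InvertedElementError as e:
        raise InvertedElementError(e.ip_index, e.det_f, event=event) from None
    w = domain.ip_weights
    f = np.zeros((domain.n_nodes, 3))
    for b in range(3):
        f += shape_table.grad[b].T @ (w[:, None] * P[:, :, b])
    return f


def total_strain_energy(state: SimState, shape_table: ShapeTable,
                        material_field: MaterialField, domain: Domain) -> float:
    """Total strain energy (kPa mm^3 = uJ) by background-cell quadrature."""
    from .constitutive import strain_energy_batch

    F = deformation_gradients(state.u, shape_table)
    W = strain_energy_batch(F, material_field.mu_eff, material_field.kappa_eff)
    return float(np.dot(domain.ip_weights, W))


def lumped_mass(domain: Domain, shape_table: ShapeTable,
                material_field: MaterialField, scaled: bool = False) -> np.ndarray:
    """Cell-corner (tributary-volume) lumped nodal masses in kg.

    Each integration point's mass w * rho is split equally over the corners of
    its background cell — the nodes within one nodal spacing in the Chebyshev
    metric — which makes every interior node carry exactly rho * h^3, keeps
    all masses positive and conserves total mass to machine precision.
    (Shape-function row-sum lumping is not usable here: the interpolating
    singular-kernel shape functions undershoot enough that row sums deviate
    from the cell mass in the interior and can turn negative at corners.)
    With ``scaled=True`` the density is multiplied by the stiffening scale
    (quasi-static mass scaling).
    """
    from scipy.spatial import cKDTree

    rho = material_field.rho * (material_field.scale if scaled else 1.0)
    mass_ip = domain.ip_weights * rho * 1e-9  # mm^3 kg/m^3 -> kg
    tree = cKDTree(domain.node_coords)
    corners = tree.query_ball_point(domain.ip_coords,
                                    0.995 * domain.nodal_spacing, p=np.inf)
    m = np.zeros(domain.n_nodes)
    for w_ip, pt, idx in zip(mass_ip, domain.ip_coords, corners):
        if not idx:
            idx = [int(tree.query(pt, k=1)[1])]
        m[idx] += w_ip / len(idx)
    if np.any(m <= 0):
        i = int(np.argmin(m))
        raise DiscretisationError(f"non-positive lumped mass {m[i]:.3e} kg at node {i}"
                                  " (node unsupported by any integration point)")
    return m


def _wave_speed(material_field: MaterialField, scaled: bool) -> np.ndarray:
    """Dilatational wave speed per integration point in mm/s."""
    rho = material_field.rho * (material_field.scale if scaled else 1.0)
    modulus = material_field.kappa_eff + 4.0 * material_field.mu_eff / 3.0  # kPa
    return np.sqrt(modulus * 1e3 / rho) * 1e3


def stable_timestep(domain: Domain, material_field: MaterialField,
                    safety: float = 0.5, mass_scaled: bool = False) -> float:
    """CFL-type bound dt = safety * h_min / c_max in seconds."""
    c_max = _wave_speed(material_field, mass_scaled).max()
    return safety * domain.nodal_spacing / c_max


def step(state: SimState, forces: np.ndarray, masses: np.ndarray, dt: float,
         damping: float = 0.0) -> SimState:
    """One damped central-difference step (in place).

    ``forces`` is the net nodal force (mN); acceleration is forces/masses in
    mm/s^2. Velocities live at half steps. Fixed nodes keep u = 0 and
    prescribed components are snapped to their targets regardless of forces.
    """
    a = forces / masses[:, None]
    c = 0.5 * damping * dt
    state.v = (state.v * (1.0 - c) + dt * a) / (1.0 + c)
    state.u = state.u + dt * state.v
    state.t += dt
    if not np.all(np.isfinite(state.u)):
        raise DivergenceError("non-finite displacement during explicit step; "
                              "reduce the time step or increase damping")
    state.enforce_constraints()
    return state


class ReactionCorrection:
    """Dirichlet boundary-reaction correction for the meshfree weak form.

    Free-node test functions do not vanish between the nodes of a Dirichlet
    boundary, so a constant-stress state leaves a spurious residual
    P . s_i with s_i the discrete divergence of phi_i. Subtracting
    P(node_i) . s_i — with the stress evaluated from the nodal gradient
    tabulation — cancels that residual exactly for affine fields (the linear
    patch test) and approximates the reaction-traction surface term
    otherwise. The correction is masked off near traction-free faces, where
    the uncorrected surface term is the correct natural boundary condition.
    """

    def __init__(self, shape_table: ShapeTable, material_field: MaterialField,
                 node_mask: np.ndarray, update_every: int = 1,
                 relaxation: float = 0.1):
        s = shape_table.discrete_div
        node_mask = np.asarray(node_mask, dtype=bool)
        comp = (node_mask if node_mask.ndim == 2
                else np.repeat(node_mask[:, None], 3, axis=1))
        anym = comp.any(axis=1)
        self.active = np.flatnonzero(anym & (np.abs(s).max(axis=1) > 1e-12))
        self.comp_mask = comp[self.active]
        self.s = s[self.active]
        self.grad_rows = tuple(G[self.active] for G in shape_table.grad_nodes)
        self.material_field = material_field
        self.update_every = max(1, int(update_every))
        #: under-relaxation of the correction force: it tracks the current
        #: stress quasi-statically instead of feeding back into the explicit
        #: loop at full gain (which is destabilising)
        self.relaxation = float(relaxation)
        self.n_nodes = shape_table.n_nodes
        self._force = np.zeros((self.n_nodes, 3))

    def update(self, u: np.ndarray) -> np.ndarray:
        if self.active.size == 0:
            return self._force
        F = np.empty((self.active.size, 3, 3))
        for b in range(3):
            F[:, :, b] = self.grad_rows[b] @ u
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        F[:, 2, 2] += 1.0
        mf = self.material_field
        mu = mf.mu_n[self.active] * mf.scale_n[self.active]
        kappa = mf.kappa_n[self.active] * mf.scale_n[self.active]
        try:
            P = pk1_stress_batch(F, mu, kappa)
        except InvertedElementError:
            # transient nodal inversion: keep the previous correction
            return self._force
        target = np.einsum("iab,ib->ia", P, self.s) * self.comp_mask
        beta = self.relaxation
        self._force[self.active] = ((1.0 - beta) * self._force[self.active]
                                    + beta * target)
        return self._force


def dirichlet_reaction_correction(domain: Domain, shape_table: ShapeTable,
                                  material_field: MaterialField,
                                  free_faces: bool = True,
                                  update_every: int = 5) -> ReactionCorrection:
    """Correction masked to exclude nodes near the traction-free insertion face."""
    mask = np.ones(domain.n_nodes, dtype=bool)
    if free_faces and domain.boundary_sets["insertion_face"].size:
        axis = domain.insertion_axis
        k = int(np.argmax(np.abs(axis)))
        coords = domain.node_coords[:, k]
        face_coord = (coords.min() if axis[k] > 0 else coords.max())
        reach = (shape_table.supports.radii.max() if len(shape_table.supports)
                 else 2 * domain.nodal_spacing)
        mask &= np.abs(coords - face_coord) > reach
    return ReactionCorrection(shape_table, material_field, mask, update_every)


def default_damping(domain: Domain, material_field: MaterialField,
                    mass_scaled: bool = False) -> float:
    """Mass-proportional damping ~ critical for the estimated fundamental mode.

    The lowest mode is approximated as a shear standing wave across the largest
    domain extent: omega ~ pi c_shear / L, alpha = 2 omega.
    """
    rho = material_field.rho * (material_field.scale if mass_scaled else 1.0)
    c_shear = np.sqrt(material_field.mu_eff * 1e3 / rho).min() * 1e3  # mm/s
    L = float(np.ptp(domain.node_coords, axis=0).max())
    return 2.0 * np.pi * c_shear / L


def relax_to_equilibrium(state: SimState, shape_table: ShapeTable,
                         material_field: MaterialField, domain: Domain, *,
                         tol: float = 1e-3, max_iter: int = 3000, window: int = 50,
                         dt: float | None = None, alpha: float | None = None,
                         safety: float = 0.5, mass_scaling: bool = True,
                         masses: np.ndarray | None = None,
                         correction: ReactionCorrection | None = None,
                         ramp_steps: int = 0,
                         event: str | None = None):
    """Dynamic relaxation to the quasi-static solution.

    Iterates damped central-difference steps until the maximum nodal
    displacement increment over a trailing ``window`` of steps is <= ``tol``
    (mm), or ``max_iter`` is reached (non-fatal: the report carries the
    ``converged`` flag and the caller decides).

    With ``alpha=None`` the mass-proportional damping is adapted per window
    from a Rayleigh-quotient estimate of the currently dominant mode
    (Underwood-style adaptive dynamic relaxation), seeded by a shear-wave
    estimate of the fundamental frequency. ``ramp_steps > 0`` ramps the
    prescribed targets linearly from the entry state over that many steps,
    avoiding shock transients (and spurious element inversion) when large
    prescribed increments are applied at once.
    """
    if masses is None:
        masses = lumped_mass(domain, shape_table, material_field, scaled=mass_scaling)
    if dt is None:
        dt = stable_timestep(domain, material_field, safety=safety,
                             mass_scaled=mass_scaling)
    adaptive = alpha is None
    alpha0 = default_damping(domain, material_field, mass_scaled=mass_scaling)
    if adaptive:
        alpha = alpha0
    state.v[:] = 0.0
    state.enforce_constraints()
    ramp_targets = None
    if ramp_steps > 0 and state.prescribed_idx.size:
        ramp_targets = state.prescribed_target.copy()
        ramp_start = np.where(state.prescribed_mask,
                              state.u[state.prescribed_idx], ramp_targets)
    u_ref = state.u.copy()
    iterations = 0
    du = np.inf
    converged = False
    f = None
    f_prev = None
    f_corr = (correction.update(state.u) if correction is not None else None)
    fast = HAVE_NUMBA and correction is None
    if fast:
        csr = shape_table.grad_csr_arrays()
        p_start = (np.where(state.prescribed_mask, state.u[state.prescribed_idx],
                            state.prescribed_target)
                   if (ramp_targets is not None) else state.prescribed_target)
        p_target = (ramp_targets if ramp_targets is not None
                    else state.prescribed_target)
    while iterations < max_iter:
        u_win = state.u.copy()
        if fast:
            done, det_min, det_arg = _relax_window_kernel(
                *csr, domain.ip_weights, material_field.mu_eff,
                material_field.kappa_eff, state.u, state.v, masses, dt, alpha,
                window, state.fixed, state.prescribed_idx, p_start, p_target,
                state.prescribed_mask, iterations,
                ramp_steps if ramp_targets is not None else 0)
            if det_min <= 0.0:
                raise InvertedElementError(det_arg, det_min, event=event)
            state.t += window * dt
            if not np.all(np.isfinite(state.u)):
                raise DivergenceError("non-finite displacement during relaxation; "
                                      "reduce the time step or increase damping")
            f = -internal_forces(state, shape_table, material_field, domain,
                                 event=event)
        else:
            for j in range(window):
                if ramp_targets is not None:
                    frac = min(1.0, (iterations + j + 1) / ramp_steps)
                    state.prescribed_target = (ramp_start
                                               + frac * (ramp_targets - ramp_start))
                if correction is not None and j % correction.update_every == 0:
                    f_corr = correction.update(state.u)
                f = -internal_forces(state, shape_table, material_field, domain,
                                     event=event)
                if f_corr is not None:
                    f = f + f_corr
                step(state, f, masses, dt, alpha)
        iterations += window
        du = float(np.abs(state.u - u_ref).max())
        if du <= tol and iterations >= ramp_steps:
            converged = True
            break
        u_ref = state.u.copy()
        if adaptive and f_prev is not None:
            d = state.u - u_win
            num = abs(float(np.sum(d * (f - f_prev))))
            den = float(np.sum(masses[:, None] * d * d))
            if den > 0.0 and num > 0.0:
                # critical damping of the dominant transient mode, kept within
                # a band of the seed estimate for robustness
                alpha = min(max(2.0 * np.sqrt(num / den), 0.05 * alpha0), 50.0 * alpha0)
        f_prev = f
    if ramp_targets is not None:
        state.prescribed_target = ramp_targets
        state.enforce_constraints()
    ke = float(0.5 * np.sum(masses[:, None] * state.v**2))
    return state, RelaxationReport(iterations=iterations, kinetic_energy=ke,
                                   displacement_increment=du, converged=converged)
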