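"""Near-incompressible Neo-Hookean hyperelasticity and spatial material fields.

The strain energy uses the decoupled (J-split) form

    W(F) = mu/2 (J^(-2/3) tr(F^T F) - 3) + kappa/2 (J - 1)^2,   J = det F,

with shear modulus mu and bulk modulus kappa in kPa. The first
Piola-Kirchhoff stress is the analytic derivative

    P = mu J^(-2/3) (F - tr(F^T F)/3 F^-T) + kappa J (J - 1) F^-T.

Spatial heterogeneity (prostate vs surrounding tissue) and needle-induced
stiffening are carried by a :class:`MaterialField`: each integration point has
a base material by region plus a multiplicative stiffening scale s >= 1 that
multiplies both moduli (density is never scaled). Scales compose by maximum,
never by product, so overlapping anchor and catheter stiffening saturates at
the stiffening factor instead of compounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, InvertedElementError
from .phantom import REGION_PROSTATE, REGION_SURROUNDING, Domain

__all__ = [
    "Material",
    "MaterialField",
    "strain_energy",
    "pk1_stress",
    "strain_energy_batch",
    "pk1_stress_batch",
    "effective_material",
    "DEFAULT_MATERIALS",
]


@dataclass(frozen=True)
class Material:
    """Homogeneous near-incompressible Neo-Hookean material.

    shear_modulus, bulk_modulus in kPa; density in kg/m^3. Requires
    kappa/mu >= 10 (near-incompressibility).
    """

    shear_modulus: float
    bulk_modulus: float
    density: float = 1000.0

    def __post_init__(self):
        if self.shear_modulus <= 0 or self.bulk_modulus <= 0:
            raise InputError("moduli must be positive")
        if self.bulk_modulus / self.shear_modulus < 10.0:
            raise InputError("near-incompressibility requires kappa/mu >= 10")
        if self.density <= 0:
            raise InputError("density must be positive")

    @classmethod
    def from_young_poisson(cls, young: float, poisson: float,
                           density: float = 1000.0) -> "Material":
        """Construct from Young's modulus E (kPa) and Poisson ratio nu."""
        mu = young / (2.0 * (1.0 + poisson))
        kappa = young / (3.0 * (1.0 - 2.0 * poisson))
        return cls(mu, kappa, density)

    @property
    def young(self) -> float:
        mu, k = self.shear_modulus, self.bulk_modulus
        return 9.0 * k * mu / (3.0 * k + mu)

    @property
    def poisson(self) -> float:
        mu, k = self.shear_modulus, self.bulk_modulus
        return (3.0 * k - 2.0 * mu) / (2.0 * (3.0 * k + mu))

    def scaled(self, s: float) -> "Material":
        """Moduli multiplied by s; density unchanged."""
        return Material(self.shear_modulus * s, self.bulk_modulus * s, self.density)


#: default tissue parameters: mid-range prostate elastography values
DEFAULT_MATERIALS = {
    REGION_PROSTATE: Material.from_young_poisson(25.0, 0.49),
    REGION_SURROUNDING: Material.from_young_poisson(10.0, 0.49),
}


class MaterialField:
    """Per-integration-point material with a multiplicative stiffening scale.

    A parallel set of nodal arrays (``mu_n``, ``kappa_n``, ``scale_n``) carries
    the same material description at the nodes, where the solver evaluates
    stress for the Dirichlet reaction correction.
    """

    def __init__(self, mu: np.ndarray, kappa: np.ndarray, rho: np.ndarray,
                 scale: np.ndarray | None = None, nodal: tuple | None = None):
        self.mu = np.asarray(mu, dtype=float)
        self.kappa = np.asarray(kappa, dtype=float)
        self.rho = np.asarray(rho, dtype=float)
        self.scale = (np.ones_like(self.mu) if scale is None
                      else np.asarray(scale, dtype=float))
        if np.any(self.scale < 1.0):
            raise InputError("stiffening scales must be >= 1")
        if nodal is None:
            self.mu_n = self.kappa_n = self.scale_n = None
        else:
            self.mu_n, self.kappa_n, self.scale_n = (np.asarray(a, dtype=float)
                                                     for a in nodal)

    @classmethod
    def from_domain(cls, domain: Domain, materials: dict | None = None) -> "MaterialField":
        materials = materials or DEFAULT_MATERIALS
        mu = np.full(domain.n_ips, np.nan)
        kappa = np.full(domain.n_ips, np.nan)
        rho = np.full(domain.n_ips, np.nan)
        mu_n = np.full(domain.n_nodes, np.nan)
        kappa_n = np.full(domain.n_nodes, np.nan)
        for region, m in materials.items():
            sel = domain.ip_region == region
            mu[sel] = m.shear_modulus
            kappa[sel] = m.bulk_modulus
            rho[sel] = m.density
            seln = domain.node_region == region
            mu_n[seln] = m.shear_modulus
            kappa_n[seln] = m.bulk_modulus
        if np.isnan(mu).any() or np.isnan(mu_n).any():
            raise InputError("materials must cover every region present in the domain")
        return cls(mu, kappa, rho,
                   nodal=(mu_n, kappa_n, np.ones(domain.n_nodes)))

    @property
    def mu_eff(self) -> np.ndarray:
        return self.mu * self.scale

    @property
    def kappa_eff(self) -> np.ndarray:
        return self.kappa * self.scale

    def stiffen(self, indices: np.ndarray, factor: float,
                node_indices: np.ndarray | None = None) -> None:
        """Apply scale s <- max(s, factor) on the given integration points
        (and, when supplied, the matching nodes)."""
        if factor < 1.0:
            raise InputError("stiffening factor must be >= 1")
        self.scale[indices] = np.maximum(self.scale[indices], factor)
        if node_indices is not None and self.scale_n is not None:
            self.scale_n[node_indices] = np.maximum(self.scale_n[node_indices], factor)

    def copy(self) -> "MaterialField":
        nodal = (None if self.mu_n is None
                 else (self.mu_n.copy(), self.kappa_n.copy(), self.scale_n.copy()))
        return MaterialField(self.mu.copy(), self.kappa.copy(), self.rho.copy(),
                             self.scale.copy(), nodal=nodal)


def effective_material(field: MaterialField, ip: int) -> Material:
    """Base material at integration point ``ip`` with its stiffening scale applied."""
    return Material(field.mu_eff[ip], field.kappa_eff[ip], field.rho[ip])


def _det3(F: np.ndarray) -> np.ndarray:
    return (F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
            - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
            + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]))


def _inv_transpose3(F: np.ndarray, J: np.ndarray) -> np.ndarray:
    """F^-T for stacked 3x3 matrices via the adjugate."""
    cof = np.empty_like(F)
    cof[..., 0, 0] = F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1]
    cof[..., 0, 1] = F[..., 1, 2] * F[..., 2, 0] - F[..., 1, 0] * F[..., 2, 2]
    cof[..., 0, 2] = F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]
    cof[..., 1, 0] = F[..., 0, 2] * F[..., 2, 1] - F[..., 0, 1] * F[..., 2, 2]
    cof[..., 1, 1] = F[..., 0, 0] * F[..., 2, 2] - F[..., 0, 2] * F[..., 2, 0]
    cof[..., 1, 2] = F[..., 0, 1] * F[..., 2, 0] - F[..., 0, 0] * F[..., 2, 1]
    cof[..., 2, 0] = F[..., 0, 1] * F[..., 1, 2] - F[..., 0, 2] * F[..., 1, 1]
    cof[..., 2, 1] = F[..., 0, 2] * F[..., 1, 0] - F[..., 0, 0] * F[..., 1, 2]
    cof[..., 2, 2] = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return cof / J[..., None, None]


def strain_energy_batch(F: np.ndarray, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Energy density (kPa) for stacked deformation gradients; det F must be > 0."""
    F = np.asarray(F, dtype=float)
    J = _det3(F)
    if np.any(J <= 0):
        i = int(np.argmin(J))
        raise InvertedElementError(i, float(J.flat[i] if J.ndim else J))
    I1 = np.einsum("...ij,...ij->...", F, F)
    return 0.5 * mu * (J ** (-2.0 / 3.0) * I1 - 3.0) + 0.5 * kappa * (J - 1.0) ** 2


def pk1_stress_batch(F: np.ndarray, mu, kappa) -> np.ndarray:
    """First Piola-Kirchhoff stress (kPa) for stacked deformation gradients."""
    F = np.asarray(F, dtype=float)
    J = _det3(F)
    if np.any(J <= 0):
        i = int(np.argmin(J))
        raise InvertedElementError(i, float(J.flat[i] if J.ndim else J))
    Fit = _inv_transpose3(F, J)
    I1 = np.einsum("...ij,...ij->...", F, F)
    mu = np.asarray(mu, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    iso = (mu * J ** (-2.0 / 3.0))[..., None, None] * (F - (I1 / 3.0)[..., None, None] * Fit)
    vol = (kappa * J * (J - 1.0))[..., None, None] * Fit
    return iso + vol


def strain_energy(F: np.ndarray, m: Material) -> float:
    """Strain-energy density W(F) in kPa; zero iff F is a rotation."""
    return float(strain_energy_batch(np.asarray(F, dtype=float),
                                     m.shear_modulus, m.bulk_modulus))


def pk1_stress(F: np.ndarray, m: Material) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF in kPa; P(I) = 0."""
    return pk1_stress_batch(np.asarray(F, dtype=float),
                            m.shear_modulus, m.bulk_modulus)
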