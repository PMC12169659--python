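"""IEF-PCM boundary-element solvent model.

The solvent is a structureless dielectric outside a molecule-shaped cavity
built from scaled van der Waals spheres.  The electrostatics reduces to a
boundary integral problem on the cavity surface Gamma for the apparent
surface charge sigma(s):

    [(2 pi f_eps) I - D] S sigma = (-2 pi I + D) phi^rho

with the single-layer (S) and double-layer (D) kernels, the molecular
electrostatic potential phi^rho (nuclear + electronic), and the permittivity
prefactor f_eps = (eps + 1)/(eps - 1).

Discretization: each sphere carries a near-uniform Fibonacci-spiral point
set with equal base weights; points buried in neighbouring spheres are
smoothly switched off (erf switching on the signed distance to each foreign
sphere surface), so energies vary continuously with geometry.  Diagonal
regularization S_kk = 1.0694 sqrt(4 pi / a_k); D_kk fixed row-wise by the
discrete Gauss identity sum_j D_kj a_j = -2 pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .basis import ANG2BOHR, ELEMENT_Z
from .integrals import potential_integrals

# Bondi van der Waals radii (Angstrom)
BONDI_RADII = {"H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52,
               "F": 1.47, "Ne": 1.54, "P": 1.80, "S": 1.80, "Cl": 1.75}

WATER_EPS = 78.3553


@dataclass
class PCMConfig:
    epsilon: float = WATER_EPS
    radii_scale: float = 1.2
    points_per_sphere: int = 590
    radii_set: str = "bondi"
    switch_width: float = 0.2      # Angstrom
    zeta_tilde: float = 4.9        # Gaussian blur factor (surface charges)
    radii_override: dict = field(default_factory=dict)


@dataclass
class Cavity:
    centers: np.ndarray        # (nsph, 3) bohr
    radii: np.ndarray          # (nsph,) bohr
    points: np.ndarray         # (npts, 3) bohr
    areas: np.ndarray          # (npts,) bohr^2 (switched weights included)
    normals: np.ndarray        # (npts, 3) outward unit
    sphere_index: np.ndarray   # owning sphere per point
    zetas: np.ndarray = None   # Gaussian blur exponents (bohr^-1)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_csv(self, sigma=None) -> str:
        hdr = "x,y,z,area,nx,ny,nz" + (",sigma" if sigma is not None else "")
        rows = [hdr]
        for k in range(self.n_points):
            row = list(self.points[k]) + [self.areas[k]] + list(self.normals[k])
            if sigma is not None:
                row.append(sigma[k])
            rows.append(",".join(f"{v:.10g}" for v in row))
        return "\n".join(rows) + "\n"


@dataclass
class PCMOperators:
    S: np.ndarray
    D: np.ndarray
    areas: np.ndarray
    f_eps: float
    epsilon: float


@dataclass
class SurfaceCharge:
    sigma: np.ndarray          # pointwise surface-charge density (a.u.)
    charges: np.ndarray        # sigma * area (apparent point charges)
    potential: np.ndarray      # generating phi^rho at the points


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_cavity(elements, coords_bohr, config: PCMConfig | None = None
                 ) -> Cavity:
    """Scaled-vdW-sphere cavity with switched surface quadrature."""
    cfg = config or PCMConfig()
    coords_bohr = np.atleast_2d(np.asarray(coords_bohr, float))
    radii = []
    for el in elements:
        r = cfg.radii_override.get(el)
        if r is None:
            if cfg.radii_set != "bondi":
                raise ValueError(f"unknown radii set '{cfg.radii_set}'")
            r = BONDI_RADII[el]
        radii.append(r * cfg.radii_scale * ANG2BOHR)
    radii = np.array(radii)
    w_sw = cfg.switch_width * ANG2BOHR
    pts, areas, normals, owner, zetas = [], [], [], [], []
    unit = fibonacci_sphere(cfg.points_per_sphere)
    w_quad = np.sqrt(4.0 * np.pi / cfg.points_per_sphere)
    for i, (c, R) in enumerate(zip(coords_bohr, radii)):
        p = c + R * unit
        w = np.ones(len(p))
        for j, (cj, Rj) in enumerate(zip(coords_bohr, radii)):
            if j == i:
                continue
            d = np.linalg.norm(p - cj, axis=1)
            w *= 0.5 * (1.0 + erf((d - Rj) / w_sw))
        keep = w > 1e-12
        pts.append(p[keep])
        areas.append(w[keep] * 4.0 * np.pi * R * R / cfg.points_per_sphere)
        normals.append(unit[keep])
        owner.append(np.full(int(keep.sum()), i))
        zetas.append(np.full(int(keep.sum()), cfg.zeta_tilde / (R * w_quad)))
    pts = np.vstack(pts)
    if len(pts) == 0:
        raise RuntimeError("cavity has no exposed surface points")
    return Cavity(centers=coords_bohr, radii=radii, points=pts,
                  areas=np.concatenate(areas), normals=np.vstack(normals),
                  sphere_index=np.concatenate(owner),
                  zetas=np.concatenate(zetas))


def assemble_operators(cavity: Cavity, epsilon: float) -> PCMOperators:
    """Discretized single- and double-layer kernels on the cavity surface."""
    if epsilon < 1.0:
        raise ValueError("epsilon must be >= 1")
    s = cavity.points
    a = cavity.areas
    n = cavity.normals
    npts = len(s)
    diff = s[:, None, :] - s[None, :, :]           # s_k - s_j
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist[~np.eye(npts, dtype=bool)] < 1e-10):
        raise RuntimeError("coincident cavity surface points")
    np.fill_diagonal(dist, 1.0)
    # Gaussian-blurred surface charges: pairwise kernel erf(z r)/r keeps
    # close contacts between points of different spheres finite and smooth
    if cavity.zetas is not None:
        z = cavity.zetas
        zij = z[:, None] * z[None, :] / np.sqrt(z[:, None] ** 2
                                                + z[None, :] ** 2)
        ef = erf(zij * dist)
        gauss = 2.0 * zij / np.sqrt(np.pi) * np.exp(-(zij * dist) ** 2)
    else:
        ef = np.ones((npts, npts))
        gauss = np.zeros((npts, npts))
    S = ef / dist
    np.fill_diagonal(S, 1.0694 * np.sqrt(4.0 * np.pi / a))
    # D_kj = d/dn_j [erf(z r)/r], r = |s_j - s_k| (plain kernel: -n.(r)/r^3)
    proj = np.einsum("kjd,jd->kj", diff, n)        # n_j . (s_k - s_j)
    D = proj * (ef / dist ** 3 - gauss / dist ** 2)
    np.fill_diagonal(D, 0.0)
    # Gauss identity: sum_j D_kj a_j = -2 pi  fixes the diagonal
    np.fill_diagonal(D, (-2.0 * np.pi - D @ a) / a)
    f_eps = np.inf if epsilon == 1.0 else (epsilon + 1.0) / (epsilon - 1.0)
    return PCMOperators(S=S, D=D, areas=a, f_eps=f_eps, epsilon=epsilon)


def response_matrix(ops: PCMOperators, symmetrize: bool = True) -> np.ndarray:
    """Q mapping surface potentials to apparent point charges q = Q phi."""
    if np.isinf(ops.f_eps):
        return np.zeros((len(ops.areas), len(ops.areas)))
    A = np.diag(ops.areas)
    DA = ops.D * ops.areas[None, :]
    K = (2.0 * np.pi * ops.f_eps * np.eye(len(ops.areas)) - DA) \
        @ ops.S @ A
    R = -2.0 * np.pi * np.eye(len(ops.areas)) + DA
    Q = A @ np.linalg.solve(K, R)
    if symmetrize:
        Q = 0.5 * (Q + Q.T)
    return Q


def solve_surface_charge(ops: PCMOperators, potential) -> SurfaceCharge:
    """Solve the IEF-PCM linear system for pointwise sigma."""
    phi = np.asarray(potential, float)
    if phi.shape[0] != len(ops.areas):
        raise ValueError("potential/operator point-set mismatch")
    if np.isinf(ops.f_eps):            # eps = 1: no dielectric response
        z = np.zeros_like(phi)
        return SurfaceCharge(sigma=z, charges=z.copy(), potential=phi)
    A = np.diag(ops.areas)
    K = (2.0 * np.pi * ops.f_eps * np.eye(len(ops.areas))
         - ops.D * ops.areas[None, :]) @ ops.S @ A
    rhs = (-2.0 * np.pi * np.eye(len(ops.areas))
           + ops.D * ops.areas[None, :]) @ phi
    cond = np.linalg.cond(K)
    if cond > 1e14:
        raise RuntimeError(f"singular IEF-PCM system (cond ~ {cond:.2e})")
    sigma = np.linalg.solve(K, rhs)
    resid = np.linalg.norm(K @ sigma - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-10:
        raise RuntimeError(f"IEF-PCM solve residual {resid:.2e}")
    return SurfaceCharge(sigma=sigma, charges=sigma * ops.areas,
                         potential=phi)


def polarization_energy(charge: SurfaceCharge, potential=None) -> float:
    """E_pol = 1/2 sum_k q_k phi_k (Hartree)."""
    phi = charge.potential if potential is None else np.asarray(potential)
    if phi.shape != charge.charges.shape:
        raise ValueError("dimension mismatch")
    return 0.5 * float(charge.charges @ phi)


def solvent_operator(charge: SurfaceCharge, shells, pot_ints=None):
    """Fold apparent charges into a one-electron operator + nuclear scalar.

    Returns (V_mat, none_scalar_hook): V_mat[mu,nu] = -sum_k q_k (mu|1/|r-s_k||nu)
    acting on the electron density; the nuclear interaction scalar must be
    added by the caller as sum_k q_k phi_nuc(s_k) (it depends on the nuclei,
    not on the basis).
    """
    if pot_ints is None:
        raise ValueError("pot_ints (potential integrals at cavity points) "
                         "required")
    return -np.tensordot(charge.charges, pot_ints, axes=(0, 0))


# ---------------------------------------------------------------------------
# assembled per-geometry context used by SCF and the CI solver
# ---------------------------------------------------------------------------


class PCMContext:
    """Cavity + operators + precomputed potential integrals for a molecule."""

    def __init__(self, elements, coords_bohr, nuclear_charges, shells,
                 config: PCMConfig | None = None):
        self.config = config or PCMConfig()
        self.cavity = build_cavity(elements, coords_bohr, self.config)
        self.ops = assemble_operators(self.cavity, self.config.epsilon)
        self.Q = response_matrix(self.ops, symmetrize=True)
        Z = np.asarray(nuclear_charges, float)
        d = np.linalg.norm(self.cavity.points[:, None, :]
                           - np.atleast_2d(coords_bohr)[None, :, :], axis=2)
        self.phi_nuc = (1.0 / d) @ Z
        self.pot_ints = potential_integrals(shells, self.cavity.points)
        self.shells = shells

    def surface_potential(self, dm) -> np.ndarray:
        """phi^rho at the cavity points for AO density dm (electrons > 0)."""
        return self.phi_nuc - np.tensordot(self.pot_ints, dm,
                                           axes=([1, 2], [0, 1]))

    def charges_for(self, dm) -> SurfaceCharge:
        phi = self.surface_potential(dm)
        q = self.Q @ phi
        a = self.ops.areas
        return SurfaceCharge(sigma=q / a, charges=q, potential=phi)

    def scf_hook(self, dm):
        """(V_solvent, e_pol) for the SCF loop; variational in G."""
        sc = self.charges_for(dm)
        V = -np.tensordot(sc.charges, self.pot_ints, axes=(0, 0))
        return V, polarization_energy(sc)


def make_solvent_factory(config: PCMConfig | None = None, basis_name="cc-pvdz"):
    """solvent(mol) -> SCF hook factory used by geometry optimization."""
    from .basis import build_shells

    def factory(mol):
        shells = build_shells(mol.elements, mol.coords_bohr, basis_name)
        ctx = PCMContext(mol.elements, mol.coords_bohr, mol.charges,
                         shells, config)
        return ctx.scf_hook

    return factory
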