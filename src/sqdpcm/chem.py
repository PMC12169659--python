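"""Molecular setup: geometries, mean field, active spaces, integrals.

The supported workflow is neutral closed-shell solutes (restricted
reference).  Active spaces are chosen either with the atomic-valence (AVAS)
projection onto a minimal reference basis, or as "all orbitals minus a
frozen core" (the convention used for small-molecule full-valence spaces).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize

from . import basis as _basis
from .basis import ANG2BOHR, ELEMENT_Z, ao_labels, build_shells
from .integrals import overlap_kinetic
from .scf import SCFResult, rhf

HARTREE2KCAL = 627.509474


# ---------------------------------------------------------------------------
# molecule
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    elements: list
    coordinates: np.ndarray          # Angstrom
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.elements) != len(self.coordinates):
            raise ValueError("element/coordinate count mismatch")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.charge != 0 or self.multiplicity != 1:
            raise ValueError(
                "only neutral closed-shell solutes are supported")

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coordinates * ANG2BOHR

    @property
    def charges(self) -> np.ndarray:
        return np.array([ELEMENT_Z[e] for e in self.elements], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    def to_xyz(self, comment="") -> str:
        lines = [str(len(self.elements)), comment]
        for el, (x, y, z) in zip(self.elements, self.coordinates):
            lines.append(f"{el:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_xyz(cls, text: str) -> "Molecule":
        lines = text.strip().splitlines()
        nat = int(lines[0].split()[0])
        elems, coords = [], []
        for ln in lines[2:2 + nat]:
            parts = ln.split()
            elems.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        return cls(elems, np.array(coords))


def run_rhf(mol: Molecule, basis_name: str = "cc-pvdz",
            solvent_hook=None, dm0=None, int_cache=None) -> SCFResult:
    shells = build_shells(mol.elements, mol.coords_bohr, basis_name)
    return rhf(shells, mol.charges, mol.coords_bohr, mol.n_electrons,
               solvent_hook=solvent_hook, dm0=dm0, int_cache=int_cache)


# ---------------------------------------------------------------------------
# active spaces
# ---------------------------------------------------------------------------


@dataclass
class ActiveSpace:
    n_electrons: int
    n_orbitals: int
    orbital_coefficients: np.ndarray      # (nbf, n_orbitals), occ first
    frozen_core: list = field(default_factory=list)
    core_coefficients: np.ndarray | None = None   # (nbf, n_core)

    def __post_init__(self):
        if self.n_electrons % 2:
            raise ValueError("only spin-balanced active spaces supported")
        if self.n_orbitals < self.n_electrons // 2:
            raise ValueError("more electron pairs than active orbitals")

    @property
    def n_alpha(self) -> int:
        return self.n_electrons // 2

    n_beta = n_alpha


def hilbert_dimension(active_space) -> int:
    """Determinant count C(n_orb, n_alpha) * C(n_orb, n_beta)."""
    if isinstance(active_space, tuple):
        ne, no = active_space
    else:
        ne, no = active_space.n_electrons, active_space.n_orbitals
    if ne % 2:
        raise ValueError("odd electron numbers are unsupported")
    na = ne // 2
    return math.comb(no, na) ** 2


def _match_ao_labels(labels, selectors):
    """Indices of AOs whose '<n><l>' tag on element El matches 'El <n><l>'."""
    idx = []
    for i, lab in enumerate(labels):
        _, el, tag = lab.split(maxsplit=2)
        for sel in selectors:
            sel_el, sel_tag = sel.split()
            if el == sel_el and tag.startswith(sel_tag):
                idx.append(i)
                break
    return idx


def select_active_space_avas(scf_res: SCFResult, ao_selectors,
                             mol: Molecule, threshold: float = 0.2,
                             ref_basis: str = "sto-3g") -> ActiveSpace:
    """Atomic valence active space from projection onto minimal-basis AOs.

    ao_selectors are strings like "C 2s", "O 2p", "H 1s".  Occupied and
    virtual canonical orbitals are rotated separately to diagonalize the
    projector onto the selected reference AOs; orbitals with overlap
    eigenvalue above ``threshold`` become active.
    """
    shells_ref = build_shells(mol.elements, mol.coords_bohr, ref_basis)
    labels = ao_labels(shells_ref, mol.elements)
    sel = _match_ao_labels(labels, ao_selectors)
    if not sel:
        raise ValueError(f"no reference AOs match {ao_selectors}")
    # cross overlaps from a combined shell list
    shells_mol = scf_res.shells
    combined = list(shells_mol) + list(shells_ref)
    off = 0
    for sh in combined:
        sh2 = sh
        sh2.ao_offset = off
        off += sh2.n_sph
    coff = 0
    for sh in combined:
        sh.cart_offset = coff
        coff += sh.n_cart
    S_full, _ = overlap_kinetic(combined)
    n1 = sum(sh.n_sph for sh in shells_mol)
    # restore offsets of the molecular shells
    off = coff = 0
    for sh in shells_mol:
        sh.ao_offset = off
        sh.cart_offset = coff
        off += sh.n_sph
        coff += sh.n_cart
    S12 = S_full[:n1, n1:][:, sel]
    S22 = S_full[n1:, n1:][np.ix_(sel, sel)]
    P = S12 @ np.linalg.solve(S22, S12.T)    # projector metric in AO basis

    C = scf_res.mo_coeff
    nocc = scf_res.n_occ
    wocc, Uocc = eigh(C[:, :nocc].T @ P @ C[:, :nocc])
    wvir, Uvir = eigh(C[:, nocc:].T @ P @ C[:, nocc:])
    wocc, Uocc = wocc[::-1], Uocc[:, ::-1]
    wvir, Uvir = wvir[::-1], Uvir[:, ::-1]
    n_act_occ = int(np.sum(wocc > threshold))
    n_act_vir = int(np.sum(wvir > threshold))
    Cocc = C[:, :nocc] @ Uocc
    Cvir = C[:, nocc:] @ Uvir
    core = Cocc[:, n_act_occ:]               # weak-overlap occupied = core
    act = np.hstack([Cocc[:, :n_act_occ][:, ::-1], Cvir[:, :n_act_vir]])
    return ActiveSpace(
        n_electrons=2 * n_act_occ,
        n_orbitals=n_act_occ + n_act_vir,
        orbital_coefficients=act,
        frozen_core=list(range(nocc - n_act_occ)),
        core_coefficients=core,
    )


def select_active_space_frozen_core(scf_res: SCFResult,
                                    n_frozen: int) -> ActiveSpace:
    """All canonical orbitals active except the lowest n_frozen."""
    C = scf_res.mo_coeff
    nocc = scf_res.n_occ
    nmo = C.shape[1]
    return ActiveSpace(
        n_electrons=2 * (nocc - n_frozen),
        n_orbitals=nmo - n_frozen,
        orbital_coefficients=C[:, n_frozen:],
        frozen_core=list(range(n_frozen)),
        core_coefficients=C[:, :n_frozen],
    )


# ---------------------------------------------------------------------------
# active-space Hamiltonian
# ---------------------------------------------------------------------------


@dataclass
class MOHamiltonian:
    h1: np.ndarray            # (norb, norb), Hartree
    h2: np.ndarray            # (norb,)*4 chemists' (pq|rs), 8-fold symmetric
    e_core: float             # nuclear repulsion + frozen-core energy
    n_electrons: int
    n_orbitals: int
    # hooks for electrostatic potentials of active-space densities
    shells: list | None = None
    mo_active: np.ndarray | None = None      # (nbf, norb)
    dm_core: np.ndarray | None = None        # AO core density (doubly occ.)

    def __post_init__(self):
        if not np.allclose(self.h1, self.h1.T, atol=1e-10):
            raise ValueError("h1 not symmetric")


def build_active_hamiltonian(scf_res: SCFResult,
                             active: ActiveSpace) -> MOHamiltonian:
    """Effective (h1, h2, e_core) for the active window over the RHF core."""
    Ca = active.orbital_coefficients
    if Ca.shape[0] != scf_res.hcore.shape[0]:
        raise ValueError("orbital/basis dimension mismatch")
    G4 = scf_res.eri4
    H = scf_res.hcore
    if active.core_coefficients is not None and \
            active.core_coefficients.shape[1] > 0:
        Dc = 2.0 * active.core_coefficients @ active.core_coefficients.T
    else:
        Dc = np.zeros_like(H)
    J = np.tensordot(G4, Dc, axes=([2, 3], [0, 1]))
    K = np.tensordot(G4, Dc, axes=([1, 3], [0, 1]))
    Vc = J - 0.5 * K
    h1 = Ca.T @ (H + Vc) @ Ca
    e_core = scf_res.e_nuc + np.sum(Dc * H) + 0.5 * np.sum(Dc * Vc)
    g = G4
    for _ in range(4):
        g = np.tensordot(Ca, g, axes=(0, 3))
    return MOHamiltonian(h1=0.5 * (h1 + h1.T),
                         h2=np.ascontiguousarray(g),
                         e_core=float(e_core),
                         n_electrons=active.n_electrons,
                         n_orbitals=active.n_orbitals,
                         shells=scf_res.shells,
                         mo_active=Ca,
                         dm_core=Dc)


# ---------------------------------------------------------------------------
# geometry optimization (numerical gradients, quasi-Newton)
# ---------------------------------------------------------------------------


def optimize_geometry(mol: Molecule, basis_name: str = "cc-pvdz",
                      solvent=None, gtol: float = 3e-4,
                      max_steps: int = 200, fd_step: float = 5e-3,
                      callback=None) -> Molecule:
    """Minimize the RHF (optionally solvated) energy over nuclear positions.

    Central-difference gradients in Cartesian bohr; converged when the
    largest gradient component falls below ``gtol`` (Hartree/bohr).
    ``solvent`` is a factory ``solvent(mol) -> hook`` so the cavity follows
    the geometry.
    """
    state = {"dm": None}

    def energy(x):
        m = Molecule(mol.elements, (x.reshape(-1, 3) / ANG2BOHR).copy())
        hook = solvent(m) if solvent is not None else None
        res = run_rhf(m, basis_name, solvent_hook=hook, dm0=state["dm"])
        state["dm"] = res.dm
        return res.e_tot

    def grad(x):
        g = np.zeros_like(x)
        for i in range(len(x)):
            xp = x.copy()
            xp[i] += fd_step
            ep = energy(xp)
            xm = x.copy()
            xm[i] -= fd_step
            em = energy(xm)
            g[i] = (ep - em) / (2 * fd_step)
        return g

    x0 = mol.coords_bohr.ravel().copy()
    # quasi-Newton stalls from line-search precision loss are cleared by
    # restarting with a fresh Hessian from the current point
    res = None
    for _ in range(6):
        res = minimize(energy, x0, jac=grad, method="BFGS",
                       callback=callback,
                       options={"gtol": gtol, "maxiter": max_steps,
                                "norm": np.inf})
        x0 = res.x
        if np.max(np.abs(res.jac)) <= gtol:
            break
    if np.max(np.abs(res.jac)) > gtol:
        raise RuntimeError(
            f"geometry optimization did not converge: "
            f"max |g| = {np.max(np.abs(res.jac)):.2e} Hartree/bohr")
    return Molecule(mol.elements, res.x.reshape(-1, 3) / ANG2BOHR)


# ---------------------------------------------------------------------------
# FCIDUMP
# ---------------------------------------------------------------------------


def write_fcidump(ham: MOHamiltonian, path, tol=1e-12):
    n = ham.n_orbitals
    with open(path, "w") as f:
        f.write(f"&FCI NORB={n},NELEC={ham.n_electrons},MS2=0,\n")
        f.write("  ORBSYM=" + "1," * n + "\n")
        f.write("  ISYM=1,\n&END\n")
        for p in range(n):
            for q in range(p + 1):
                for r in range(p + 1):
                    smax = q if r == p else r
                    for s in range(smax + 1):
                        v = ham.h2[p, q, r, s]
                        if abs(v) > tol:
                            f.write(f"{v:23.16e} {p+1:4d} {q+1:4d} "
                                    f"{r+1:4d} {s+1:4d}\n")
        for p in range(n):
            for q in range(p + 1):
                v = ham.h1[p, q]
                if abs(v) > tol:
                    f.write(f"{v:23.16e} {p+1:4d} {q+1:4d}    0    0\n")
        f.write(f"{ham.e_core:23.16e}    0    0    0    0\n")


def read_fcidump(path) -> MOHamiltonian:
    with open(path) as f:
        text = f.read()
    head, _, body = text.partition("&END")
    import re
    n = int(re.search(r"NORB\s*=\s*(\d+)", head).group(1))
    ne = int(re.search(r"NELEC\s*=\s*(\d+)", head).group(1))
    h1 = np.zeros((n, n))
    h2 = np.zeros((n, n, n, n))
    e_core = 0.0
    for ln in body.strip().splitlines():
        parts = ln.split()
        if len(parts) != 5:
            continue
        v = float(parts[0])
        p, q, r, s = (int(t) for t in parts[1:])
        if p == 0:
            e_core = v
        elif r == 0:
            h1[p - 1, q - 1] = h1[q - 1, p - 1] = v
        else:
            p, q, r, s = p - 1, q - 1, r - 1, s - 1
            for a, b, c, d in ((p, q, r, s), (q, p, r, s), (p, q, s, r),
                               (q, p, s, r), (r, s, p, q), (s, r, p, q),
                               (r, s, q, p), (s, r, q, p)):
                h2[a, b, c, d] = v
    return MOHamiltonian(h1=h1, h2=h2, e_core=e_core, n_electrons=ne,
                         n_orbitals=n)
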