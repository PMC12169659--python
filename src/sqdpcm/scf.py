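"""Restricted Hartree-Fock with DIIS, with an optional reaction-field hook.

The solvent hook makes RHF-in-solvent a one-line extension: any callable
``hook(D) -> (V_mat, e_pol)`` receiving the AO density matrix and returning
the solvent one-electron operator and the polarization energy is folded into
the Fock matrix, which keeps the converged solution variational in the free
energy G = E[rho] + 1/2 <sigma, phi(rho)>.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .integrals import eri, nuclear_attraction, overlap_kinetic


@dataclass
class SCFResult:
    e_tot: float              # total energy (free energy G if solvated)
    e_pol: float              # solvent polarization term, 0 in gas phase
    e_nuc: float
    mo_coeff: np.ndarray      # (nbf, nmo)
    mo_energy: np.ndarray
    dm: np.ndarray            # total (doubly occupied) density matrix
    n_occ: int
    converged: bool
    shells: list
    ovlp: np.ndarray
    hcore: np.ndarray
    eri4: np.ndarray
    n_iter: int = 0


def nuclear_repulsion(Z, R) -> float:
    e = 0.0
    for i in range(len(Z)):
        for j in range(i):
            e += Z[i] * Z[j] / np.linalg.norm(R[i] - R[j])
    return e


def _orthogonalizer(S, thresh=1e-9):
    w, v = eigh(S)
    keep = w > thresh
    return v[:, keep] / np.sqrt(w[keep])


def rhf(shells, Z, R, n_elec, solvent_hook=None, conv_tol=1e-10,
        max_iter=200, dm0=None, int_cache=None):
    """Closed-shell RHF.  ``int_cache`` may carry (S, T, V, eri4) to reuse."""
    if n_elec % 2:
        raise ValueError("restricted closed-shell RHF requires even n_elec")
    n_occ = n_elec // 2
    if int_cache is None:
        S, T = overlap_kinetic(shells)
        V = nuclear_attraction(shells, np.asarray(Z, float), np.asarray(R))
        G4 = eri(shells)
    else:
        S, T, V, G4 = int_cache
    H = T + V
    X = _orthogonalizer(S)
    e_nuc = nuclear_repulsion(Z, R)

    def fock_build(D):
        J = np.tensordot(G4, D, axes=([2, 3], [0, 1]))
        K = np.tensordot(G4, D, axes=([1, 3], [0, 1]))
        return J - 0.5 * K

    if dm0 is None:
        # core-Hamiltonian guess
        e, c = eigh(X.T @ H @ X)
        C = X @ c
        D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    else:
        D = dm0

    diis_f, diis_e = [], []
    e_old = 0.0
    e_pol = 0.0
    converged = False
    mo_e = None
    C = None
    for it in range(max_iter):
        G = fock_build(D)
        F = H + G
        if solvent_hook is not None:
            Vs, e_pol = solvent_hook(D)
            F = F + Vs
        # DIIS
        err = F @ D @ S - S @ D @ F
        err = X.T @ err @ X
        diis_f.append(F.copy())
        diis_e.append(err.ravel())
        if len(diis_f) > 8:
            diis_f.pop(0)
            diis_e.pop(0)
        if len(diis_f) > 1:
            n = len(diis_f)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = diis_e[i] @ diis_e[j]
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:n]
                F = sum(wi * fi for wi, fi in zip(w, diis_f))
            except np.linalg.LinAlgError:
                pass
        mo_e, c = eigh(X.T @ F @ X)
        C = X @ c
        D_new = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        e_el = np.sum(D_new * H) + 0.5 * np.sum(D_new * fock_build(D_new))
        e_tot = e_el + e_nuc + e_pol
        if abs(e_tot - e_old) < conv_tol and \
                np.max(np.abs(D_new - D)) < 1e-7:
            D = D_new
            converged = True
            e_old = e_tot
            break
        D = D_new
        e_old = e_tot
    if not converged:
        raise RuntimeError(
            f"SCF failed to converge in {max_iter} iterations "
            f"(last E = {e_old:.10f})")
    return SCFResult(e_tot=e_old, e_pol=e_pol, e_nuc=e_nuc, mo_coeff=C,
                     mo_energy=mo_e, dm=D, n_occ=n_occ, converged=converged,
                     shells=shells, ovlp=S, hcore=H, eri4=G4, n_iter=it + 1)
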