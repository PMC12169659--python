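"""Closed-shell CCSD in the active space (spin-orbital formulation).

Provides the gas-phase t1/t2 amplitudes that parameterize the LUCJ ansatz.
Plain amplitude iteration with damping-free updates and energy-based
convergence; adequate for the modest active spaces sampled here.  The
spin-orbital equations are the standard single-reference CCSD working
equations with full (possibly non-diagonal) Fock contributions.
"""

from __future__ import annotations

import numpy as np

from .chem import MOHamiltonian


def _spin_orbital_integrals(ham: MOHamiltonian):
    """<pq||rs> (physicists', antisymmetrized) over interleaved spin
    orbitals 2p+sigma, plus the Fock matrix of the reference determinant."""
    n = ham.n_orbitals
    nso = 2 * n
    # physicists <pq|rs> = (pr|qs)_chem, spin deltas on (p,r) and (q,s)
    eri_phys = ham.h2.transpose(0, 2, 1, 3)
    g = np.zeros((nso,) * 4)
    for sp in (0, 1):
        for sq in (0, 1):
            g[sp::2, sq::2, sp::2, sq::2] = eri_phys
    aso = g - g.transpose(0, 1, 3, 2)
    h = np.zeros((nso, nso))
    h[::2, ::2] = ham.h1
    h[1::2, 1::2] = ham.h1
    no = ham.n_electrons  # spin-orbitals occupied (interleaved: first no)
    f = h + np.einsum("piqi->pq", aso[:, :no, :, :no])
    return aso, f, no


def run_ccsd(ham: MOHamiltonian, max_iter: int = 200, conv: float = 1e-9):
    """Returns (e_corr, t1, t2) with *spatial* restricted amplitudes
    t1[i,a], t2[i,j,a,b] (opposite spin)."""
    aso, f, no = _spin_orbital_integrals(ham)
    nso = aso.shape[0]
    nv = nso - no
    o = slice(0, no)
    v = slice(no, nso)
    eps = np.diag(f)
    Dia = eps[o, None] - eps[None, v]
    Dijab = (eps[o, None, None, None] + eps[None, o, None, None]
             - eps[None, None, v, None] - eps[None, None, None, v])
    if np.min(np.abs(Dia)) < 1e-8 or np.min(np.abs(Dijab)) < 1e-8:
        raise RuntimeError("vanishing orbital-energy denominator in CCSD")
    t1 = f[o, v] / Dia
    t2 = aso[o, o, v, v] / Dijab

    def energy(t1, t2):
        e = np.einsum("ia,ia->", f[o, v], t1)
        e += 0.25 * np.einsum("ijab,ijab->", aso[o, o, v, v], t2)
        e += 0.5 * np.einsum("ijab,ia,jb->", aso[o, o, v, v], t1, t1)
        return e

    e_old = energy(t1, t2)
    for it in range(max_iter):
        tau_t = t2 + 0.5 * (np.einsum("ia,jb->ijab", t1, t1)
                            - np.einsum("ib,ja->ijab", t1, t1))
        tau = t2 + (np.einsum("ia,jb->ijab", t1, t1)
                    - np.einsum("ib,ja->ijab", t1, t1))
        Fae = f[v, v] - np.diag(np.diag(f[v, v]))
        Fae -= 0.5 * np.einsum("me,ma->ae", f[o, v], t1)
        Fae += np.einsum("mf,mafe->ae", t1, aso[o, v, v, v])
        Fae -= 0.5 * np.einsum("mnaf,mnef->ae", tau_t, aso[o, o, v, v])
        Fmi = f[o, o] - np.diag(np.diag(f[o, o]))
        Fmi += 0.5 * np.einsum("ie,me->mi", t1, f[o, v])
        Fmi += np.einsum("nf,mnif->mi", t1, aso[o, o, o, v])
        Fmi += 0.5 * np.einsum("inef,mnef->mi", tau_t, aso[o, o, v, v])
        Fme = f[o, v] + np.einsum("nf,mnef->me", t1, aso[o, o, v, v])
        Wmnij = aso[o, o, o, o].copy()
        Wmnij += np.einsum("je,mnie->mnij", t1, aso[o, o, o, v])
        Wmnij -= np.einsum("ie,mnje->mnij", t1, aso[o, o, o, v])
        Wmnij += 0.25 * np.einsum("ijef,mnef->mnij", tau, aso[o, o, v, v])
        Wabef = aso[v, v, v, v].copy()
        Wabef -= np.einsum("mb,amef->abef", t1, aso[v, o, v, v])
        Wabef += np.einsum("ma,bmef->abef", t1, aso[v, o, v, v])
        Wabef += 0.25 * np.einsum("mnab,mnef->abef", tau, aso[o, o, v, v])
        Wmbej = aso[o, v, v, o].copy()
        Wmbej += np.einsum("jf,mbef->mbej", t1, aso[o, v, v, v])
        Wmbej -= np.einsum("nb,mnej->mbej", t1, aso[o, o, v, o])
        tmp = 0.5 * t2 + np.einsum("jf,nb->jnfb", t1, t1)
        Wmbej -= np.einsum("jnfb,mnef->mbej", tmp, aso[o, o, v, v])

        rhs1 = f[o, v].copy()
        rhs1 += np.einsum("ie,ae->ia", t1, Fae)
        rhs1 -= np.einsum("ma,mi->ia", t1, Fmi)
        rhs1 += np.einsum("imae,me->ia", t2, Fme)
        rhs1 -= np.einsum("nf,naif->ia", t1, aso[o, v, o, v])
        rhs1 -= 0.5 * np.einsum("imef,maef->ia", t2, aso[o, v, v, v])
        rhs1 -= 0.5 * np.einsum("mnae,nmei->ia", t2, aso[o, o, v, o])
        t1_new = rhs1 / Dia

        rhs2 = aso[o, o, v, v].copy()
        tFae = Fae - 0.5 * np.einsum("mb,me->be", t1, Fme)
        x = np.einsum("ijae,be->ijab", t2, tFae)
        rhs2 += x - x.transpose(0, 1, 3, 2)
        tFmi = Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme)
        x = np.einsum("imab,mj->ijab", t2, tFmi)
        rhs2 -= x - x.transpose(1, 0, 2, 3)
        rhs2 += 0.5 * np.einsum("mnab,mnij->ijab", tau, Wmnij)
        rhs2 += 0.5 * np.einsum("ijef,abef->ijab", tau, Wabef)
        x = np.einsum("imae,mbej->ijab", t2, Wmbej)
        x -= np.einsum("ie,ma,mbej->ijab", t1, t1, aso[o, v, v, o])
        x = x - x.transpose(0, 1, 3, 2)
        x = x - x.transpose(1, 0, 2, 3)
        rhs2 += x
        x = np.einsum("ie,abej->ijab", t1, aso[v, v, v, o])
        rhs2 += x - x.transpose(1, 0, 2, 3)
        x = np.einsum("ma,mbij->ijab", t1, aso[o, v, o, o])
        rhs2 -= x - x.transpose(0, 1, 3, 2)
        t2_new = rhs2 / Dijab

        t1, t2 = t1_new, t2_new
        e = energy(t1, t2)
        if abs(e - e_old) < conv:
            e_old = e
            break
        e_old = e
    else:
        raise RuntimeError("CCSD did not converge")
    # spatial restricted amplitudes: alpha singles, alpha-beta doubles
    t1_sp = t1[0::2, 0::2]
    t2_sp = t2[0::2, 1::2, 0::2, 1::2]
    return float(e_old), t1_sp, t2_sp
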