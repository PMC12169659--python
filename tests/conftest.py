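"""Shared fixtures: tiny molecules, their mean fields and active spaces."""

import numpy as np
import pytest

from sqdpcm.chem import (Molecule, build_active_hamiltonian, run_rhf,
                         select_active_space_frozen_core)


@pytest.fixture(scope="session")
def h2():
    return Molecule(["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, 0.7414]])


@pytest.fixture(scope="session")
def water():
    return Molecule(["O", "H", "H"],
                    [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692],
                     [0.0, -0.7572, -0.4692]])


@pytest.fixture(scope="session")
def h2_sto3g(h2):
    res = run_rhf(h2, "sto-3g")
    ham = build_active_hamiltonian(
        res, select_active_space_frozen_core(res, 0))
    return res, ham


@pytest.fixture(scope="session")
def h2_ccpvdz(h2):
    res = run_rhf(h2, "cc-pvdz")
    ham = build_active_hamiltonian(
        res, select_active_space_frozen_core(res, 0))
    return res, ham


@pytest.fixture(scope="session")
def water_mini(water):
    """(6e,5o) STO-3G active space of water."""
    res = run_rhf(water, "sto-3g")
    ham = build_active_hamiltonian(
        res, select_active_space_frozen_core(res, 2))
    return res, ham


def random_symmetric_integrals(norb, seed=0):
    """Random h1/g with the full 8-fold permutational symmetry."""
    rng = np.random.default_rng(seed)
    h1 = rng.normal(size=(norb, norb))
    h1 = h1 + h1.T
    g = rng.normal(size=(norb,) * 4)
    g = g + g.transpose(1, 0, 2, 3)
    g = g + g.transpose(0, 1, 3, 2)
    g = g + g.transpose(2, 3, 0, 1)
    return h1, g / 8.0


def dense_sector_hamiltonian(h1, g, norb, na, nb):
    """Brute-force sector Hamiltonian from Fock-space ladder operators.

    Fully independent of the string-CI machinery: second-quantized
    operators are built as dense 2^(2*norb) matrices (spin orbital p_alpha
    = bit p, p_beta = bit norb + p) and the Hamiltonian is assembled from
    the operator products, then restricted to the (na, nb) sector ordered
    as (alpha string) x (beta string), both ascending.
    """
    import scipy.sparse as sp

    from sqdpcm.ci import make_strings
    n_so = 2 * norb
    dim = 2 ** n_so
    ann = []
    for p in range(n_so):
        rows, cols, vals = [], [], []
        for ket in range(dim):
            if (ket >> p) & 1:
                sgn = (-1) ** bin(ket & ((1 << p) - 1)).count("1")
                rows.append(ket & ~(1 << p))
                cols.append(ket)
                vals.append(sgn)
        ann.append(sp.csr_matrix((vals, (rows, cols)), shape=(dim, dim)))
    crt = [a.T.tocsr() for a in ann]
    H = sp.csr_matrix((dim, dim))
    for p in range(norb):
        for q in range(norb):
            for s0 in (0, norb):
                H = H + h1[p, q] * (crt[p + s0] @ ann[q + s0])
    for p in range(norb):
        for q in range(norb):
            for r in range(norb):
                for s in range(norb):
                    if g[p, q, r, s] == 0.0:
                        continue
                    for s1 in (0, norb):
                        for s2 in (0, norb):
                            H = H + 0.5 * g[p, q, r, s] * (
                                crt[p + s1] @ crt[r + s2]
                                @ ann[s + s2] @ ann[q + s1])
    sa = make_strings(norb, na)
    sb = make_strings(norb, nb)
    idx = np.array([int(A) | (int(B) << norb) for A in sa for B in sb])
    return H.toarray()[np.ix_(idx, idx)]
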