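"""Boundary-element PCM checks: analytic Born ion, Gauss identity,
conductor limit, operator contracts."""

import numpy as np
import pytest

from sqdpcm.basis import ANG2BOHR, build_shells
from sqdpcm.chem import Molecule, run_rhf
from sqdpcm.integrals import potential_integrals
from sqdpcm.pcm import (PCMConfig, PCMContext, assemble_operators,
                        build_cavity, polarization_energy,
                        solve_surface_charge, solvent_operator)

EPS = 78.3553


def born_cavity(n_points, a_bohr=2.0):
    cfg = PCMConfig(points_per_sphere=n_points, radii_scale=1.0,
                    radii_override={"H": a_bohr / ANG2BOHR})
    return build_cavity(["H"], [[0.0, 0.0, 0.0]], cfg)


def born_epol(n_points, eps=EPS, a=2.0, q=1.0):
    cav = born_cavity(n_points, a)
    ops = assemble_operators(cav, eps)
    phi = q / np.linalg.norm(cav.points, axis=1)
    sc = solve_surface_charge(ops, phi)
    return polarization_energy(sc), sc, ops


def test_born_ion_analytic():
    e, _, _ = born_epol(590)
    ref = -0.5 * (1 - 1 / EPS) / 2.0
    assert abs(e / ref - 1) < 0.005


def test_born_error_decreases_with_points():
    ref = -0.5 * (1 - 1 / EPS) / 2.0
    errs = [abs(born_epol(n)[0] - ref) for n in (110, 302, 590)]
    assert errs[0] > errs[1] > errs[2]


def test_conductor_limit_total_charge():
    _, sc, _ = born_epol(590, eps=1e6)
    assert abs(sc.charges.sum() + 1.0) < 0.01
    _, sc, _ = born_epol(590, eps=EPS)
    assert abs(sc.charges.sum() + (EPS - 1) / EPS) < 0.01


def test_eps_one_gives_zero_charge():
    cav = born_cavity(110)
    ops = assemble_operators(cav, 1.0)
    phi = 1.0 / np.linalg.norm(cav.points, axis=1)
    sc = solve_surface_charge(ops, phi)
    assert np.all(sc.sigma == 0.0)
    assert polarization_energy(sc) == 0.0


def test_gauss_identity_rows():
    cav = born_cavity(590)
    ops = assemble_operators(cav, EPS)
    rows = ops.D @ ops.areas
    assert np.abs(rows + 2 * np.pi).max() < 0.05 * 2 * np.pi


def test_operator_symmetry_and_kernel():
    """S symmetric; far off-diagonal entries are the plain Coulomb kernel."""
    cav = born_cavity(110)
    ops = assemble_operators(cav, EPS)
    assert np.allclose(ops.S, ops.S.T, atol=1e-12)
    i, j = 0, len(cav.points) // 2
    r = np.linalg.norm(cav.points[i] - cav.points[j])
    if r > 1.0:
        assert ops.S[i, j] == pytest.approx(1.0 / r, rel=1e-6)


def test_cavity_geometry_contracts(water):
    cfg = PCMConfig(points_per_sphere=110)
    cav = build_cavity(water.elements, water.coords_bohr, cfg)
    # unit normals
    assert np.allclose(np.linalg.norm(cav.normals, axis=1), 1.0, atol=1e-12)
    assert np.all(cav.areas > 0)
    # occlusion: total area strictly below the sum of full sphere areas
    full = 4 * np.pi * (cav.radii ** 2).sum()
    assert cav.areas.sum() < full
    # single atom: full sphere area within quadrature tolerance
    cav1 = build_cavity(["O"], [[0.0, 0.0, 0.0]], cfg)
    assert cav1.areas.sum() == pytest.approx(
        4 * np.pi * cav1.radii[0] ** 2, rel=1e-10)
    # every significantly-weighted point lies outside every foreign sphere
    w = cav.areas / (4 * np.pi * cav.radii[cav.sphere_index] ** 2 / 110)
    strong = w > 0.5
    for j in range(len(cav.radii)):
        d = np.linalg.norm(cav.points[strong] - cav.centers[j], axis=1)
        assert np.all(d > cav.radii[j] - 0.3)


def test_solvent_operator_contracts(h2):
    shells = build_shells(h2.elements, h2.coords_bohr, "sto-3g")
    cfg = PCMConfig(points_per_sphere=110)
    cav = build_cavity(h2.elements, h2.coords_bohr, cfg)
    pot = potential_integrals(shells, cav.points)
    ops = assemble_operators(cav, EPS)
    # sigma = 0 -> zero operator
    from sqdpcm.pcm import SurfaceCharge
    zero = SurfaceCharge(sigma=np.zeros(cav.n_points),
                         charges=np.zeros(cav.n_points),
                         potential=np.zeros(cav.n_points))
    V = solvent_operator(zero, shells, pot_ints=pot)
    assert np.all(V == 0.0)
    # contraction identity: Tr(D V) = -sum_k q_k Tr(D v_k)
    rng = np.random.default_rng(0)
    q = rng.normal(size=cav.n_points)
    sc = SurfaceCharge(sigma=q / ops.areas, charges=q,
                       potential=np.zeros(cav.n_points))
    V = solvent_operator(sc, shells, pot_ints=pot)
    assert np.allclose(V, V.T, atol=1e-12)
    D = rng.normal(size=V.shape)
    D = D + D.T
    lhs = np.sum(D * V)
    rhs = -q @ np.tensordot(pot, D, axes=([1, 2], [0, 1]))
    assert lhs == pytest.approx(rhs, rel=1e-10)


def test_water_mirror_symmetry_of_operator(water):
    """C2v water: the solvent operator commutes with the mirror swapping
    the two hydrogens.  The spiral surface grid is not itself mirror
    symmetric, so the commutator vanishes only in the quadrature limit:
    assert monotone decay with point density and a tight bound at the
    densest grid."""
    shells = build_shells(water.elements, water.coords_bohr, "sto-3g")
    res = run_rhf(water, "sto-3g")
    # AO order: O 1s, O 2s, O 2p{y,z,x}, H1 1s, H2 1s; mirror y -> -y
    perm = [0, 1, 2, 3, 4, 6, 5]
    signs = np.ones(7)
    signs[2] = -1.0
    P = np.zeros((7, 7))
    for i, j in enumerate(perm):
        P[i, j] = signs[i]
    dev = []
    for n in (110, 302, 1202):
        ctx = PCMContext(water.elements, water.coords_bohr, water.charges,
                         shells, PCMConfig(points_per_sphere=n))
        V, _ = ctx.scf_hook(res.dm)
        dev.append(np.abs(P @ V @ P.T - V).max())
    assert dev[0] > dev[1] > dev[2]
    assert dev[2] < 1e-6


def test_cavity_csv_dump():
    cav = born_cavity(110)
    text = cav.to_csv(sigma=np.zeros(cav.n_points))
    lines = text.strip().splitlines()
    assert lines[0] == "x,y,z,area,nx,ny,nz,sigma"
    assert len(lines) == cav.n_points + 1
    assert all(len(ln.split(",")) == 8 for ln in lines[1:])
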