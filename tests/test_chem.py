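"""Molecular setup: Hilbert dimensions, IO round trips, active spaces,
geometry optimization on cheap systems."""

import numpy as np
import pytest

from sqdpcm.chem import (Molecule, build_active_hamiltonian,
                         hilbert_dimension, optimize_geometry, read_fcidump,
                         run_rhf, select_active_space_avas,
                         select_active_space_frozen_core, write_fcidump)
from sqdpcm.ci import CIEngine, make_strings, solve_ground_state


@pytest.mark.parametrize("space,dim", [
    ((14, 12), 627_264),
    ((14, 13), 2_944_656),
    ((20, 18), 1_914_762_564),
    ((8, 23), 78_411_025),
    ((2, 2), 4),
])
def test_hilbert_dimension(space, dim):
    assert hilbert_dimension(space) == dim


def test_hilbert_dimension_odd_electrons_rejected():
    with pytest.raises(ValueError):
        hilbert_dimension((3, 4))


def test_molecule_validation():
    with pytest.raises(ValueError):
        Molecule(["H"], [[0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError):
        Molecule(["H"], [[np.nan, 0, 0]])
    with pytest.raises(ValueError):
        Molecule(["H", "H"], [[0, 0, 0], [1, 0, 0]], charge=1)


def test_xyz_roundtrip(water):
    text = water.to_xyz(comment="test")
    back = Molecule.from_xyz(text)
    assert back.elements == water.elements
    assert np.allclose(back.coordinates, water.coordinates, atol=1e-9)


def test_fcidump_roundtrip(tmp_path, water_mini):
    _, ham = water_mini
    path = tmp_path / "f.dump"
    write_fcidump(ham, path)
    back = read_fcidump(path)
    assert back.n_orbitals == ham.n_orbitals
    assert back.n_electrons == ham.n_electrons
    assert np.abs(back.h1 - ham.h1).max() < 1e-12
    assert np.abs(back.h2 - ham.h2).max() < 1e-12
    assert back.e_core == pytest.approx(ham.e_core, abs=1e-12)


def test_active_hamiltonian_symmetries(water_mini):
    _, ham = water_mini
    assert np.allclose(ham.h1, ham.h1.T, atol=1e-10)
    g = ham.h2
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
        assert np.abs(g - g.transpose(perm)).max() < 1e-10


def test_reference_determinant_energy_invariant_to_core_split(water):
    """Freezing orbitals moves energy into e_core such that the reference
    determinant total energy is unchanged."""
    res = run_rhf(water, "sto-3g")
    for n_frozen in (0, 1, 2):
        act = select_active_space_frozen_core(res, n_frozen)
        ham = build_active_hamiltonian(res, act)
        na = act.n_electrons // 2
        mask = (1 << na) - 1
        eng = CIEngine(np.array([mask]), ham.n_orbitals, na)
        eng.set_integrals(ham.h1, ham.h2)
        e_det = eng.diagonal()[0, 0] + ham.e_core
        assert e_det == pytest.approx(res.e_tot, abs=1e-8)


def test_full_sector_ci_equals_direct_fci(water_mini):
    """(6e,5o) active CASCI from the engine vs dense diagonalization."""
    res, ham = water_mini
    eng = CIEngine(make_strings(5, 3), 5, 3)
    eng.set_integrals(ham.h1, ham.h2)
    e, _ = solve_ground_state(eng, tol=1e-10)
    n = eng.n_str
    H = np.zeros((n * n, n * n))
    for i in range(n * n):
        v = np.zeros(n * n)
        v[i] = 1.0
        H[:, i] = eng.matvec(v.reshape(n, n)).ravel()
    assert e == pytest.approx(np.linalg.eigvalsh(H)[0], abs=1e-9)
    assert e + ham.e_core < res.e_tot  # correlation lowers the energy


def test_avas_full_projection_selects_everything(water):
    """Projecting onto the full computational basis keeps all orbitals."""
    res = run_rhf(water, "sto-3g")
    act = select_active_space_avas(
        res, ["O 1s", "O 2s", "O 2p", "H 1s"], water, ref_basis="sto-3g")
    assert act.n_orbitals == res.mo_coeff.shape[1]
    assert act.n_electrons == water.n_electrons


def test_avas_orthonormal_orbitals(water):
    res = run_rhf(water, "cc-pvdz")
    act = select_active_space_avas(res, ["O 2s", "O 2p", "H 1s"], water)
    C = act.orbital_coefficients
    assert np.abs(C.T @ res.ovlp @ C - np.eye(C.shape[1])).max() < 1e-10
    assert act.n_electrons == 8  # 1s core of O excluded by the projector


def test_avas_empty_selection_fails(water):
    res = run_rhf(water, "sto-3g")
    with pytest.raises(ValueError):
        select_active_space_avas(res, ["C 2s"], water)


def test_optimize_h2_fixed_point(h2):
    """An already-converged geometry passes through unchanged."""
    opt1 = optimize_geometry(h2, "sto-3g", gtol=3e-4)
    opt2 = optimize_geometry(opt1, "sto-3g", gtol=3e-4)
    assert np.abs(opt2.coordinates - opt1.coordinates).max() < 2e-3


def test_optimize_h2_against_grid_scan():
    """Optimized bond length vs a dense 1-D energy scan (to 1e-3 A)."""
    mol = Molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.0584]])  # 2 bohr start
    opt = optimize_geometry(mol, "sto-3g", gtol=1e-5)
    r_opt = np.linalg.norm(opt.coordinates[1] - opt.coordinates[0])
    rs = np.linspace(0.65, 0.80, 151)
    energies = []
    for r in rs:
        m = Molecule(["H", "H"], [[0, 0, 0], [0, 0, r]])
        energies.append(run_rhf(m, "sto-3g").e_tot)
    # parabola through the scan minimum
    k = int(np.argmin(energies))
    c = np.polyfit(rs[k - 2:k + 3], energies[k - 2:k + 3], 2)
    r_scan = -c[1] / (2 * c[0])
    assert abs(r_opt - r_scan) < 1e-3


def test_water_full_valence_minus_core_space(water):
    """All cc-pVDZ orbitals active except the oxygen 1s core: (8e,23o)."""
    res = run_rhf(water, "cc-pvdz")
    act = select_active_space_frozen_core(res, 1)
    assert act.n_electrons == 8
    assert act.n_orbitals == 23
    assert hilbert_dimension(act) == 78_411_025
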