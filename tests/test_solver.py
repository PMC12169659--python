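"""Projected SCRF solver: projection contracts, gas-phase reduction,
independent variational oracle for the reaction-field ground state."""

import numpy as np
import pytest
from scipy.optimize import minimize

from sqdpcm.chem import HARTREE2KCAL
from sqdpcm.ci import CIEngine, make_strings
from sqdpcm.pcm import PCMConfig, PCMContext
from sqdpcm.recovery import ConfigurationSubspace
from sqdpcm.solver import (ProjectedProblem, SolvatedResult, gsolv,
                           select_best_batch, solve_scrf_ground_state)

from conftest import dense_sector_hamiltonian


def test_single_determinant_projection(water_mini):
    _, ham = water_mini
    na = ham.n_electrons // 2
    mask = (1 << na) - 1
    sub = ConfigurationSubspace(np.array([mask]), ham.n_orbitals, na)
    prob = ProjectedProblem.build(ham, sub)
    res = solve_scrf_ground_state(prob, None)
    # equals <x_RHF|H|x_RHF>
    diag = prob.engine.diagonal()[0, 0]
    assert res.E == pytest.approx(diag + ham.e_core, abs=1e-10)


def test_full_projection_is_casci(water_mini):
    _, ham = water_mini
    prob = ProjectedProblem.build(ham, None)
    res = solve_scrf_ground_state(prob, None, davidson_tol=1e-9)
    Hd = dense_sector_hamiltonian(ham.h1, ham.h2, ham.n_orbitals, 3, 3)
    assert res.E == pytest.approx(np.linalg.eigvalsh(Hd)[0] + ham.e_core,
                                  abs=1e-8)


def test_empty_subspace_rejected(water_mini):
    _, ham = water_mini
    with pytest.raises(ValueError):
        ProjectedProblem.build(
            ham, ConfigurationSubspace(np.array([], dtype=np.int64),
                                       ham.n_orbitals, 3))


def test_scrf_matches_direct_variational_oracle(water, water_mini):
    """The SCRF fixed point must minimize
    G(c) = c.H0 c + 1/2 q(c).phi(c); checked against direct numerical
    minimization over the full (6e,5o) CI vector (d = 100)."""
    scf_res, ham = water_mini
    ctx = PCMContext(water.elements, water.coords_bohr, water.charges,
                     scf_res.shells, PCMConfig(points_per_sphere=110))
    prob = ProjectedProblem.build(ham, None)
    res = solve_scrf_ground_state(prob, ctx, tol_e=1e-10, tol_q=1e-8,
                                  davidson_tol=1e-9)

    # independent functional: dense H0, explicit response matrix
    Hd = dense_sector_hamiltonian(ham.h1, ham.h2, ham.n_orbitals, 3, 3)
    from sqdpcm.solver import _active_coupling
    pot_act, pot_core = _active_coupling(ham, ctx)
    eng = CIEngine(make_strings(ham.n_orbitals, 3), ham.n_orbitals, 3)
    eng.set_integrals(ham.h1, ham.h2)
    n = eng.n_str

    def free_energy(c):
        c = c / np.linalg.norm(c)
        C = c.reshape(n, n)
        ga, gb = eng.rdm1_spin(C)
        gamma = ga + gb
        phi = ctx.phi_nuc - pot_core - np.tensordot(
            pot_act, gamma, axes=([1, 2], [0, 1]))
        q = ctx.Q @ phi
        return float(c @ Hd @ c) + ham.e_core + 0.5 * float(q @ phi)

    x0 = res.psi.ravel() + 1e-3 * np.random.default_rng(0).normal(
        size=n * n)
    out = minimize(free_energy, x0, method="BFGS",
                   options={"gtol": 1e-7, "maxiter": 500})
    assert res.E == pytest.approx(free_energy(out.x), abs=1e-6)
    assert res.E <= free_energy(out.x) + 1e-6


def test_eps_one_bitwise_gas_reduction(water_mini, water):
    scf_res, ham = water_mini
    ctx = PCMContext(water.elements, water.coords_bohr, water.charges,
                     scf_res.shells, PCMConfig(epsilon=1.0,
                                               points_per_sphere=110))
    prob = ProjectedProblem.build(ham, None)
    res_gas = solve_scrf_ground_state(prob, None)
    prob2 = ProjectedProblem.build(ham, None)
    res_eps1 = solve_scrf_ground_state(prob2, ctx)
    assert res_eps1.E == res_gas.E  # bit-for-bit
    assert res_eps1.g_pol == 0.0


def test_variational_nesting_with_solvent(water, water_mini):
    """Growing subspace chain: the gas-phase component of E is
    non-increasing along S1 in S2 in full."""
    scf_res, ham = water_mini
    na = 3
    full = make_strings(ham.n_orbitals, na)
    chains = [full[:3], full[:6], full]
    es = []
    for U in chains:
        sub = ConfigurationSubspace(np.array(U), ham.n_orbitals, na)
        prob = ProjectedProblem.build(ham, sub)
        res = solve_scrf_ground_state(prob, None)
        es.append(res.E)
    assert es[0] >= es[1] >= es[2]


def _mk(E, idx=0):
    return SolvatedResult(E=E, G_solv=None, psi=None, occupancies=None,
                          scrf_log=[], converged=True, e_gas_component=E,
                          g_pol=0.0, charges=None, subspace=None,
                          batch_index=idx)


def test_select_best_batch():
    with pytest.raises(ValueError):
        select_best_batch([])
    a, b = _mk(-115.10, 0), _mk(-115.12, 1)
    assert select_best_batch([a, b]) is b
    assert select_best_batch([a]) is a
    # ties broken by batch index
    c, d = _mk(-1.0, 0), _mk(-1.0, 1)
    assert select_best_batch([c, d]) is c


def test_gsolv_conventions():
    r = _mk(-100.01)
    r.g_pol = -0.008
    assert gsolv(r, -100.0) == pytest.approx(-0.01 * HARTREE2KCAL)
    assert gsolv(r, 0.0, "polarization") == pytest.approx(
        -0.008 * HARTREE2KCAL)
    with pytest.raises(ValueError):
        gsolv(r, 0.0, "bogus")
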