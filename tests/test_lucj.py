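"""LUCJ derivation, exact sector simulation, sampling and noise."""

import numpy as np
import pytest
import scipy.linalg as sla

from sqdpcm.ccsd import run_ccsd
from sqdpcm.ci import make_strings, occ_array, solve_ground_state, CIEngine
from sqdpcm.lucj import (LUCJParameters, SampleSet, derive_lucj_from_ccsd,
                         inject_noise, sample_bitstrings,
                         simulate_lucj_state)

from conftest import dense_sector_hamiltonian


def test_ccsd_exact_for_two_electrons(h2_ccpvdz):
    """CCSD is exact for a 2-electron system: total energy equals FCI."""
    res, ham = h2_ccpvdz
    e_corr, t1, t2 = run_ccsd(ham)
    eng = CIEngine(make_strings(ham.n_orbitals, 1), ham.n_orbitals, 1)
    eng.set_integrals(ham.h1, ham.h2)
    e_fci, _ = solve_ground_state(eng, tol=1e-10)
    assert res.e_tot + e_corr == pytest.approx(e_fci + ham.e_core, abs=1e-8)


def test_zero_t2_gives_rotated_single_determinant(h2_sto3g):
    _, ham = h2_sto3g
    nocc, nvir = 1, ham.n_orbitals - 1
    t1 = np.zeros((nocc, nvir))
    t2 = np.zeros((nocc, nocc, nvir, nvir))
    p = derive_lucj_from_ccsd(t1, t2)
    assert np.all(p.Jaa == 0) and np.all(p.Jab == 0)
    psi, masks = simulate_lucj_state(p, 1)
    i0 = int(np.searchsorted(masks, 1))
    assert abs(psi[i0, i0]) == pytest.approx(1.0, abs=1e-12)


def test_derivation_deterministic(h2_ccpvdz):
    _, ham = h2_ccpvdz
    _, t1, t2 = run_ccsd(ham)
    p1 = derive_lucj_from_ccsd(t1, t2)
    p2 = derive_lucj_from_ccsd(t1, t2)
    assert np.array_equal(p1.K1, p2.K1)
    assert np.array_equal(p1.Jaa, p2.Jaa)
    assert np.array_equal(p1.K2, p2.K2)


def test_h2_fidelity_above_99_percent(h2_sto3g):
    """The (2e,2o) LUCJ state from CCSD amplitudes overlaps the FCI ground
    state with fidelity > 0.99 (here: to machine precision)."""
    _, ham = h2_sto3g
    _, t1, t2 = run_ccsd(ham)
    params = derive_lucj_from_ccsd(t1, t2)
    psi, _ = simulate_lucj_state(params, 1)
    eng = CIEngine(make_strings(2, 1), 2, 1)
    eng.set_integrals(ham.h1, ham.h2)
    _, C = solve_ground_state(eng, tol=1e-10)
    fid = abs(np.vdot(psi.ravel(), C.ravel())) ** 2
    assert fid > 0.99


def test_simulation_matches_dense_operator_exponential():
    """(4e,4o) with random small parameters vs a brute-force Fock-space
    construction of the same circuit."""
    norb, na = 4, 2
    rng = np.random.default_rng(12)
    A = rng.normal(size=(norb, norb)) + 1j * rng.normal(size=(norb, norb))
    K1 = 0.1 * (A - A.conj().T)
    B = rng.normal(size=(norb, norb))
    K2 = 0.05 * (B - B.T) + 0j
    J = rng.normal(size=(norb, norb)) * 0.2
    Jaa = 0.5 * (J + J.T)
    Jab = np.outer(rng.normal(size=norb), np.ones(norb)) * 0.1
    Jab = 0.5 * (Jab + Jab.T)
    params = LUCJParameters(K1=K1, Jaa=Jaa, Jab=Jab, K2=K2, n_occ=na)
    psi, masks = simulate_lucj_state(params, na)

    # dense oracle over the full Fock space
    n_so = 2 * norb
    dim = 2 ** n_so
    ann = []
    for p in range(n_so):
        a = np.zeros((dim, dim))
        for ket in range(dim):
            if (ket >> p) & 1:
                sgn = (-1) ** bin(ket & ((1 << p) - 1)).count("1")
                a[ket & ~(1 << p), ket] = sgn
        ann.append(a)
    crt = [a.T for a in ann]

    def one_body(K):
        M = np.zeros((dim, dim), complex)
        for p in range(norb):
            for q in range(norb):
                M += K[p, q] * (crt[p] @ ann[q]
                                + crt[norb + p] @ ann[norb + q])
        return M

    x_rhf = sum(1 << p for p in range(na)) | sum(
        1 << (norb + p) for p in range(na))
    v = np.zeros(dim, complex)
    v[x_rhf] = 1.0
    v = sla.expm(-one_body(params.K1)) @ v
    # Jastrow phases on occupations
    phases = np.zeros(dim)
    for ket in range(dim):
        xa = np.array([(ket >> p) & 1 for p in range(norb)], float)
        xb = np.array([(ket >> (norb + p)) & 1 for p in range(norb)], float)
        phases[ket] = xa @ Jaa @ xa + xb @ Jaa @ xb + 2 * xa @ Jab @ xb
    v = v * np.exp(1j * phases)
    v = sla.expm(one_body(params.K1)) @ v
    v = sla.expm(-one_body(params.K2)) @ v
    sa = make_strings(norb, na)
    idx = np.array([int(A_) | (int(B_) << norb) for A_ in sa for B_ in sa])
    ref = v[idx].reshape(len(sa), len(sa))
    assert np.abs(psi - ref).max() < 1e-8


def test_state_norm_unity():
    norb, na = 5, 2
    rng = np.random.default_rng(3)
    A = rng.normal(size=(norb, norb)) + 1j * rng.normal(size=(norb, norb))
    params = LUCJParameters(K1=A - A.conj().T,
                            Jaa=np.eye(norb), Jab=np.eye(norb),
                            K2=np.zeros((norb, norb)), n_occ=na)
    psi, _ = simulate_lucj_state(params, na)
    assert np.linalg.norm(psi) == pytest.approx(1.0, abs=1e-10)


def test_noiseless_samples_conserve_symmetry(water_mini):
    _, ham = water_mini
    _, t1, t2 = run_ccsd(ham)
    params = derive_lucj_from_ccsd(t1, t2)
    psi, masks = simulate_lucj_state(params, 3)
    s = sample_bitstrings(psi, masks, 20_000, seed=5, n_orb=5)
    assert np.all(s.symmetry_ok(3, 3))
    # determinism
    s2 = sample_bitstrings(psi, masks, 20_000, seed=5, n_orb=5)
    assert np.array_equal(s.counts, s2.counts)
    assert np.array_equal(s.alpha, s2.alpha)


def test_sampling_statistics_multinomial():
    """Empirical frequencies within 3 multinomial standard errors."""
    masks = make_strings(4, 2)
    amp = np.zeros((6, 6))
    amp[0, 0], amp[1, 1], amp[2, 3], amp[4, 2] = 0.8, 0.5, 0.3, np.sqrt(
        1 - 0.8 ** 2 - 0.5 ** 2 - 0.3 ** 2)
    shots = 100_000
    s = sample_bitstrings(amp, masks, shots, seed=11, n_orb=4)
    p_expected = {(0, 0): 0.64, (1, 1): 0.25, (2, 3): 0.09}
    for (ia, ib), p in p_expected.items():
        sel = (s.alpha == masks[ia]) & (s.beta == masks[ib])
        f = s.counts[sel].sum() / shots
        se = np.sqrt(p * (1 - p) / shots)
        assert abs(f - p) < 3 * se + 1e-12


def test_concentrated_state_sampling():
    masks = make_strings(3, 1)
    amp = np.zeros((3, 3))
    amp[1, 1] = 1.0
    s = sample_bitstrings(amp, masks, 500, seed=0, n_orb=3)
    assert s.n_distinct == 1 and s.counts[0] == 500


def test_inject_noise_contracts():
    masks = make_strings(12, 6)
    s = SampleSet(alpha=[int(masks[0])], beta=[int(masks[0])],
                  counts=[50_000], n_orb=12, shots=50_000)
    assert inject_noise(s, 0.0, 1) is s
    noisy = inject_noise(s, 0.01, seed=2)
    assert noisy.shots == s.shots == noisy.counts.sum()
    # broken-symmetry fraction ~ 1 - (1-p)^(2n)
    ok = noisy.symmetry_ok(6, 6)
    frac_broken = noisy.counts[~ok].sum() / noisy.shots
    p_expect = 1 - 0.99 ** 24
    # strings with compensating double flips still count as "ok", so allow
    # a small downward bias in addition to 3 sigma binomial
    se = np.sqrt(p_expect * (1 - p_expect) / noisy.shots)
    assert frac_broken < p_expect + 3 * se
    assert frac_broken > p_expect - 3 * se - 0.01


def test_inject_noise_uniformizes_at_half():
    s = SampleSet(alpha=[0], beta=[0], counts=[40_000], n_orb=6,
                  shots=40_000)
    noisy = inject_noise(s, 0.5, seed=3)
    occ = (occ_array(noisy.alpha, 6) * noisy.counts[:, None]).sum(0)
    f = occ / noisy.shots
    se = np.sqrt(0.25 / noisy.shots)
    assert np.all(np.abs(f - 0.5) < 4 * se)


def test_sample_file_roundtrip(tmp_path):
    s = SampleSet(alpha=[3, 5], beta=[6, 3], counts=[7, 2], n_orb=3,
                  shots=9, provenance="noiseless", seed=4)
    text = s.to_text()
    back = SampleSet.from_text(text)
    assert np.array_equal(back.alpha, s.alpha)
    assert np.array_equal(back.beta, s.beta)
    assert np.array_equal(back.counts, s.counts)
    assert back.shots == 9 and back.n_orb == 3
    # missing counts tolerated as count=1
    s2 = SampleSet.from_text("101010\n")
    assert s2.counts[0] == 1 and s2.n_orb == 3
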