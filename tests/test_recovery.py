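"""S-CORE recovery, batching, spin-inversion closure, occupancy updates."""

import numpy as np
import pytest

from sqdpcm.ci import CIEngine, make_strings, occ_array
from sqdpcm.lucj import SampleSet, inject_noise
from sqdpcm.recovery import (ConfigurationSubspace, OccupancyDistribution,
                             close_under_spin_inversion, initial_occupancy,
                             partition_batches, recover_configurations,
                             update_occupancy)


def make_set(pairs, n_orb, **kw):
    a, b, c = zip(*[(p[0], p[1], p[2]) for p in pairs])
    return SampleSet(alpha=list(a), beta=list(b), counts=list(c),
                     n_orb=n_orb, shots=int(sum(c)), **kw)


def test_initial_occupancy_rhf_pattern():
    s = make_set([(0b0011, 0b0011, 10)], 4)
    occ = initial_occupancy(s, 2, 2)
    assert np.array_equal(occ.n_alpha_orb, [1, 1, 0, 0])
    assert np.array_equal(occ.n_beta_orb, [1, 1, 0, 0])


def test_initial_occupancy_weighted_mean():
    """3:1 mixture of two correct strings -> hand-computed weighted mean."""
    s = make_set([(0b0011, 0b0011, 3), (0b0101, 0b0011, 1)], 4)
    occ = initial_occupancy(s, 2, 2)
    assert np.allclose(occ.n_alpha_orb, [1.0, 0.75, 0.25, 0.0])
    assert np.allclose(occ.n_beta_orb, [1.0, 1.0, 0.0, 0.0])


def test_initial_occupancy_ignores_broken_and_fails_when_all_broken():
    s = make_set([(0b0011, 0b0011, 3), (0b0111, 0b0011, 5)], 4)
    occ = initial_occupancy(s, 2, 2)  # broken string ignored
    assert np.array_equal(occ.n_alpha_orb, [1, 1, 0, 0])
    bad = make_set([(0b0111, 0b0011, 5)], 4)
    with pytest.raises(ValueError):
        initial_occupancy(bad, 2, 2)


def test_recovery_restores_exact_counts_and_conserves_shots():
    rng = np.random.default_rng(0)
    norb, na = 12, 7
    masks = make_strings(norb, na)
    idx = rng.choice(len(masks), size=20)
    clean = make_set([(int(masks[i]), int(masks[j]), 10)
                      for i, j in zip(idx[:10], idx[10:])], norb)
    noisy = inject_noise(clean, 0.05, seed=1)
    occ = initial_occupancy(noisy, na, na)
    rec = recover_configurations(noisy, occ, seed=2)
    assert rec.shots == noisy.shots
    assert np.all(rec.symmetry_ok(na, na))


def test_recovery_idempotent_on_correct_sets():
    norb, na = 6, 3
    masks = make_strings(norb, na)
    s = make_set([(int(masks[0]), int(masks[5]), 4),
                  (int(masks[7]), int(masks[2]), 6)], norb)
    occ = initial_occupancy(s, na, na)
    rec = recover_configurations(s, occ, seed=3)
    assert sorted(zip(rec.alpha, rec.beta, rec.counts)) == \
        sorted(zip(s.alpha, s.beta, s.counts))


def test_recovery_flip_weighting_follows_distance():
    """One surplus alpha bit: the orbital with the largest |x - n| must be
    emptied most often over many seeded trials."""
    norb, na = 4, 2
    # occupancies sharply peaked on orbitals 0,1
    occ = OccupancyDistribution(np.array([0.95, 0.85, 0.15, 0.05]),
                                np.array([0.95, 0.85, 0.15, 0.05]), na, na)
    # string with surplus: alpha has 3 bits (0,1,2); weights to empty:
    # |1-n| = 0.05, 0.15, 0.85 -> orbital 2 most often
    counts = np.zeros(3)
    hits = {0: 0, 1: 1, 2: 2}
    for seed in range(2000):
        raw = make_set([(0b0111, 0b0011, 1)], norb)
        rec = recover_configurations(raw, occ, seed=seed)
        removed = [p for p in range(3) if not (int(rec.alpha[0]) >> p) & 1]
        counts[hits[removed[0]]] += 1
    # occupancy normalization rescales the weights but preserves the order
    assert counts[2] > counts[1] > counts[0]
    assert counts[2] / counts.sum() > 0.6


def test_partition_batches_deterministic_and_distinct():
    norb, na = 6, 3
    masks = make_strings(norb, na)
    s = make_set([(int(m), int(m), c + 1)
                  for c, m in enumerate(masks[:12])], norb)
    b1 = partition_batches(s, 3, 5, seed=4)
    b2 = partition_batches(s, 3, 5, seed=4)
    for x, y in zip(b1, b2):
        assert np.array_equal(x.alpha, y.alpha)
        assert np.array_equal(x.counts, y.counts)
    for x in b1:
        keys = list(zip(x.alpha, x.beta))
        assert len(keys) == len(set(keys)) == 5


def test_partition_batch_size_truncates_with_warning():
    s = make_set([(0b011, 0b011, 5)], 3)
    with pytest.warns(UserWarning):
        batches = partition_batches(s, 2, 10, seed=0)
    assert batches[0].n_distinct == 1


def test_closure_under_spin_inversion():
    # batch {(a,b)} with a != b: U = {a,b}, d = 4, contains (b,a)
    s = make_set([(0b0011, 0b0101, 1)], 4)
    sub = close_under_spin_inversion(s, 2)
    assert sub.n_half == 2 and sub.dimension == 4
    assert set(sub.half_strings) == {0b0011, 0b0101}
    # spin-symmetric batch: d = (number of distinct half-strings)^2
    s2 = make_set([(0b0011, 0b0011, 1), (0b0110, 0b0110, 1)], 4)
    sub2 = close_under_spin_inversion(s2, 2)
    assert sub2.dimension == 4
    # d >= number of batch strings, always
    rng = np.random.default_rng(5)
    masks = make_strings(8, 4)
    for trial in range(5):
        ia = rng.choice(len(masks), 10)
        ib = rng.choice(len(masks), 10)
        sb = make_set([(int(masks[i]), int(masks[j]), 1)
                       for i, j in zip(ia, ib)], 8)
        sub = close_under_spin_inversion(sb, 4)
        assert sub.dimension >= sb.n_distinct
        assert sub.dimension == sub.n_half ** 2


def test_subspace_text_roundtrip():
    sub = ConfigurationSubspace(np.array([0b0011, 0b1100]), 4, 2)
    back = ConfigurationSubspace.from_text(sub.to_text())
    assert np.array_equal(back.half_strings, sub.half_strings)
    assert back.n_orb == 4 and back.n_occ == 2


def test_update_occupancy_single_determinant():
    sub = ConfigurationSubspace(np.array([0b0011]), 4, 2)
    psi = np.ones((1, 1))
    occ = update_occupancy([psi], [sub], 2, 2)
    assert np.array_equal(occ.n_alpha_orb, [1, 1, 0, 0])


def test_update_occupancy_mean_of_two_batches():
    subA = ConfigurationSubspace(np.array([0b0011]), 4, 2)
    subB = ConfigurationSubspace(np.array([0b0101]), 4, 2)
    occ = update_occupancy([np.ones((1, 1)), np.ones((1, 1))],
                           [subA, subB], 2, 2)
    assert np.allclose(occ.n_alpha_orb, [1.0, 0.5, 0.5, 0.0])


def test_update_occupancy_matches_dense_oracle_and_sums():
    """Random 20-determinant wavefunction vs the dense diagonal-density
    oracle at 1e-12, and electron-count conservation."""
    norb, na = 6, 3
    masks = make_strings(norb, na)
    rng = np.random.default_rng(6)
    U = np.sort(rng.choice(masks, size=5, replace=False))
    sub = ConfigurationSubspace(U, norb, na)
    C = rng.normal(size=(sub.n_half, sub.n_half))
    C /= np.linalg.norm(C)
    occ = update_occupancy([C], [sub], na, na)
    O = occ_array(sub.half_strings, norb)
    ref_a = np.zeros(norb)
    ref_b = np.zeros(norb)
    for i in range(sub.n_half):
        for j in range(sub.n_half):
            ref_a += C[i, j] ** 2 * O[i]
            ref_b += C[i, j] ** 2 * O[j]
    assert np.abs(occ.n_alpha_orb - ref_a).max() < 1e-12
    assert np.abs(occ.n_beta_orb - ref_b).max() < 1e-12
    assert occ.n_alpha_orb.sum() == pytest.approx(na, abs=1e-8)
    assert occ.n_beta_orb.sum() == pytest.approx(na, abs=1e-8)
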