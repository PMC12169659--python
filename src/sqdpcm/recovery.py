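"""Self-consistent configuration recovery (S-CORE) and batch handling.

Noise-corrupted samples lose exact particle number and spin-z.  Recovery
flips bits of each corrupted shot, one at a time, until the per-spin
electron counts match the target: when a spin block has surplus electrons
an occupied orbital is emptied, on deficit a virtual orbital is filled; the
flipped orbital is drawn with probability proportional to the distance
|x_p - n_p| between the current bit and the reference occupancy n_p sigma.
Strings that already satisfy the symmetries pass through unchanged, so the
procedure is idempotent on symmetry-correct sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .ci import occ_array
from .lucj import SampleSet


@dataclass
class OccupancyDistribution:
    n_alpha_orb: np.ndarray       # mean occupation per orbital, spin alpha
    n_beta_orb: np.ndarray
    n_alpha: int                  # target electron counts
    n_beta: int

    def __post_init__(self):
        for v in (self.n_alpha_orb, self.n_beta_orb):
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError("occupancies must lie in [0, 1]")

    def normalized(self) -> "OccupancyDistribution":
        a = self.n_alpha_orb * (self.n_alpha / self.n_alpha_orb.sum())
        b = self.n_beta_orb * (self.n_beta / self.n_beta_orb.sum())
        return OccupancyDistribution(np.clip(a, 0, 1), np.clip(b, 0, 1),
                                     self.n_alpha, self.n_beta)


@dataclass
class ConfigurationSubspace:
    """Spin-inversion-closed determinant set S = U x U."""

    half_strings: np.ndarray      # sorted int64 masks, exactly n_occ bits
    n_orb: int
    n_occ: int

    def __post_init__(self):
        self.half_strings = np.unique(
            np.asarray(self.half_strings, dtype=np.int64))
        pc = np.bitwise_count(self.half_strings.astype(np.uint64))
        if len(self.half_strings) and not np.all(pc == self.n_occ):
            raise ValueError("half-strings must have exactly n_occ bits set")

    @property
    def n_half(self) -> int:
        return len(self.half_strings)

    @property
    def dimension(self) -> int:
        return self.n_half ** 2

    def to_text(self) -> str:
        lines = [f"# n_orb={self.n_orb} n_occ={self.n_occ}"]
        for m in self.half_strings:
            lines.append("".join(str((int(m) >> p) & 1)
                                 for p in range(self.n_orb)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ConfigurationSubspace":
        n_orb = n_occ = None
        masks = []
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "n_orb":
                        n_orb = int(v)
                    elif k == "n_occ":
                        n_occ = int(v)
                continue
            masks.append(sum(1 << p for p, c in enumerate(ln) if c == "1"))
        return cls(np.array(masks, dtype=np.int64), n_orb, n_occ)


def initial_occupancy(raw: SampleSet, n_alpha: int,
                      n_beta: int) -> OccupancyDistribution:
    """Counts-weighted mean occupations over symmetry-correct shots only."""
    ok = raw.symmetry_ok(n_alpha, n_beta)
    if not np.any(ok):
        raise ValueError(
            "no symmetry-correct shots to seed the occupancy distribution; "
            "reduce the noise level or increase the shot count")
    w = raw.counts[ok].astype(float)
    occ_a = occ_array(raw.alpha[ok], raw.n_orb)
    occ_b = occ_array(raw.beta[ok], raw.n_orb)
    na = (w @ occ_a) / w.sum()
    nb = (w @ occ_b) / w.sum()
    return OccupancyDistribution(na, nb, n_alpha, n_beta)


@njit(cache=True)
def _recover_block(masks, counts, occ_ref, norb, target, seed):
    """Flip bits of each shot until its popcount matches target."""
    np.random.seed(seed)
    nshot = counts.sum()
    out = np.zeros(nshot, dtype=np.int64)
    w = np.zeros(norb)
    k = 0
    for i in range(len(masks)):
        for _ in range(counts[i]):
            m = masks[i]
            cnt = 0
            for p in range(norb):
                cnt += (m >> p) & 1
            while cnt != target:
                surplus = cnt > target
                tot = 0.0
                for p in range(norb):
                    bit = (m >> p) & 1
                    if surplus and bit == 1:
                        w[p] = abs(1.0 - occ_ref[p])
                    elif (not surplus) and bit == 0:
                        w[p] = occ_ref[p]
                    else:
                        w[p] = 0.0
                    tot += w[p]
                r = np.random.random() * tot
                acc = 0.0
                sel = -1
                for p in range(norb):
                    if w[p] > 0.0:
                        sel = p
                        acc += w[p]
                        if acc >= r:
                            break
                if tot <= 0.0:
                    # degenerate weights: flip the first eligible bit
                    for p in range(norb):
                        bit = (m >> p) & 1
                        if (surplus and bit == 1) or \
                                ((not surplus) and bit == 0):
                            sel = p
                            break
                m ^= (1 << sel)
                if surplus:
                    cnt -= 1
                else:
                    cnt += 1
            out[k] = m
            k += 1
    return out


def recover_configurations(raw: SampleSet, occ: OccupancyDistribution,
                           seed: int) -> SampleSet:
    """S-CORE symmetry restoration; output shots equal input shots."""
    occn = occ.normalized()
    a = _recover_block(raw.alpha, raw.counts, occn.n_alpha_orb,
                       raw.n_orb, occ.n_alpha, seed % (2**31))
    b = _recover_block(raw.beta, raw.counts, occn.n_beta_orb,
                       raw.n_orb, occ.n_beta, (seed + 1) % (2**31))
    key = a * (1 << raw.n_orb) + b
    uniq, cnt = np.unique(key, return_counts=True)
    return SampleSet(alpha=uniq >> raw.n_orb,
                     beta=uniq & ((1 << raw.n_orb) - 1),
                     counts=cnt, n_orb=raw.n_orb, shots=raw.shots,
                     provenance="recovered", seed=seed)


def partition_batches(recovered: SampleSet, n_batches: int, batch_size: int,
                      seed: int) -> list[SampleSet]:
    """K batches of distinct strings, frequency-weighted without
    replacement inside each batch, independent across batches."""
    if recovered.n_distinct == 0:
        raise ValueError("empty sample set")
    rng = np.random.default_rng(seed)
    p = recovered.counts / recovered.counts.sum()
    size = batch_size
    if size > recovered.n_distinct:
        import warnings
        warnings.warn(
            f"batch_size {batch_size} exceeds distinct strings "
            f"{recovered.n_distinct}; batches truncated")
        size = recovered.n_distinct
    out = []
    for b in range(n_batches):
        idx = rng.choice(recovered.n_distinct, size=size, replace=False, p=p)
        idx.sort()
        cnt = recovered.counts[idx]
        out.append(SampleSet(alpha=recovered.alpha[idx],
                             beta=recovered.beta[idx],
                             counts=cnt, n_orb=recovered.n_orb,
                             shots=int(cnt.sum()),
                             provenance=f"batch{b}", seed=seed))
    return out


def close_under_spin_inversion(batch: SampleSet, n_occ: int
                               ) -> ConfigurationSubspace:
    """S^(b) = U x U with U the union of alpha and beta half-strings."""
    ok = batch.symmetry_ok(n_occ, n_occ)
    if not np.all(ok):
        raise ValueError("batch contains symmetry-broken strings")
    U = np.union1d(batch.alpha, batch.beta)
    return ConfigurationSubspace(U, batch.n_orb, n_occ)


def update_occupancy(psi_list, subspaces, n_alpha: int,
                     n_beta: int) -> OccupancyDistribution:
    """Average diagonal spin densities over the K batch wavefunctions."""
    if len(psi_list) != len(subspaces):
        raise ValueError("psi/subspace count mismatch")
    norb = subspaces[0].n_orb
    na = np.zeros(norb)
    nb = np.zeros(norb)
    for C, sub in zip(psi_list, subspaces):
        occ = occ_array(sub.half_strings, norb)
        w_a = (C ** 2).sum(axis=1)
        w_b = (C ** 2).sum(axis=0)
        na += w_a @ occ
        nb += w_b @ occ
    K = len(psi_list)
    return OccupancyDistribution(np.clip(na / K, 0, 1),
                                 np.clip(nb / K, 0, 1), n_alpha, n_beta)
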