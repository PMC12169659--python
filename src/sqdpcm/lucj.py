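"""Truncated local unitary cluster Jastrow (LUCJ) state and sampling.

The sampled state is

    |Phi> = exp(-K2) exp(K1) exp(i J1) exp(-K1) |x_RHF>

with one-body anti-Hermitian generators K1, K2 and a diagonal
density-density (Jastrow) operator J1.  Parameters are derived from
gas-phase restricted CCSD amplitudes: the doubles tensor t2[i,j,a,b] is
eigendecomposed as a matrix over (occupied, virtual) pairs and the leading
factor is kept (single Jastrow layer); its Hermitian one-body factor X is
diagonalized, X = W diag(d) W^dagger, giving K1 = log W and the
density-density couplings J = d d^T; K2 carries the singles t1.

The diagonal convention: in the K1-rotated orbital basis the Jastrow phase
on an occupation vector x (alpha block then beta block) is
exp(i x^T J_full x) with J_full = [[Jaa, Jab], [Jab, Jaa]].

Simulation is exact in the fixed-(n_alpha, n_beta) determinant sector:
one-body exponentials factorize over spins into dense string-basis matrix
exponentials; the Jastrow phase is diagonal in occupation strings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .ci import _single_links, make_strings, occ_array


@dataclass
class LUCJParameters:
    K1: np.ndarray                  # (norb, norb) anti-Hermitian
    Jaa: np.ndarray                 # same-spin density-density couplings
    Jab: np.ndarray                 # opposite-spin couplings
    K2: np.ndarray                  # final one-body rotation generator
    n_occ: int

    def __post_init__(self):
        for M in (self.K1, self.K2):
            if np.max(np.abs(M + M.conj().T)) > 1e-12:
                raise ValueError("K generators must be anti-Hermitian")
        for M in (self.Jaa, self.Jab):
            if np.max(np.abs(M - M.T)) > 1e-12:
                raise ValueError("J couplings must be symmetric")

    @property
    def norb(self) -> int:
        return self.K1.shape[0]


@dataclass
class SampleSet:
    """Bitstring samples over 2*n_orb qubits (alpha block, beta block)."""

    alpha: np.ndarray               # int64 masks, orbital 0 = bit 0
    beta: np.ndarray
    counts: np.ndarray
    n_orb: int
    shots: int
    provenance: str = "noiseless"
    seed: int | None = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.int64)
        self.beta = np.asarray(self.beta, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")
        if int(self.counts.sum()) != self.shots:
            raise ValueError("counts must sum to shots")

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def symmetry_ok(self, n_alpha: int, n_beta: int) -> np.ndarray:
        return (np.bitwise_count(self.alpha.astype(np.uint64)) == n_alpha) \
            & (np.bitwise_count(self.beta.astype(np.uint64)) == n_beta)

    def bitstring(self, i: int) -> str:
        a = [(int(self.alpha[i]) >> p) & 1 for p in range(self.n_orb)]
        b = [(int(self.beta[i]) >> p) & 1 for p in range(self.n_orb)]
        return "".join(map(str, a + b))

    def to_text(self) -> str:
        out = io.StringIO()
        out.write(f"# shots={self.shots} n_orb={self.n_orb} "
                  f"provenance={self.provenance} seed={self.seed}\n")
        for i in range(self.n_distinct):
            out.write(f"{self.bitstring(i)} {self.counts[i]}\n")
        return out.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "SampleSet":
        meta = {}
        alpha, beta, counts = [], [], []
        n_orb = None
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            parts = ln.split()
            bits = parts[0]
            cnt = int(parts[1]) if len(parts) > 1 else 1
            n_orb = len(bits) // 2
            a = sum(1 << p for p in range(n_orb) if bits[p] == "1")
            b = sum(1 << p for p in range(n_orb) if bits[n_orb + p] == "1")
            alpha.append(a)
            beta.append(b)
            counts.append(cnt)
        seed = meta.get("seed")
        return cls(np.array(alpha), np.array(beta), np.array(counts),
                   n_orb=int(meta.get("n_orb", n_orb)),
                   shots=int(meta.get("shots", int(np.sum(counts)))),
                   provenance=meta.get("provenance", "file"),
                   seed=None if seed in (None, "None") else int(seed))


# ---------------------------------------------------------------------------
# parameter derivation from CCSD amplitudes
# ---------------------------------------------------------------------------


def derive_lucj_from_ccsd(t1: np.ndarray, t2: np.ndarray) -> LUCJParameters:
    """Single-layer LUCJ parameters from restricted CCSD t1/t2 amplitudes.

    t1: (nocc, nvir); t2: (nocc, nocc, nvir, nvir) with t2[i,j,a,b] the
    opposite-spin amplitude for i->a (alpha), j->b (beta).
    """
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise ValueError("non-finite CCSD amplitudes")
    nocc, nvir = t1.shape
    norb = nocc + nvir
    A = t2.transpose(0, 2, 1, 3).reshape(nocc * nvir, nocc * nvir)
    A = 0.5 * (A + A.T)
    w, v = np.linalg.eigh(A)
    t = int(np.argmax(np.abs(w)))
    lam = w[t]
    M = v[:, t].reshape(nocc, nvir)
    if abs(lam) < 1e-14:
        K1 = np.zeros((norb, norb), complex)
        J = np.zeros((norb, norb))
    else:
        omega = np.exp(1j * np.pi / 4) if lam > 0 else np.exp(-1j * np.pi / 4)
        X = np.zeros((norb, norb), dtype=complex)
        X[:nocc, nocc:] = omega * np.sqrt(abs(lam) / 2.0) * M
        X = X + X.conj().T
        d, W = np.linalg.eigh(X)
        K1 = sla.logm(W)
        K1 = 0.5 * (K1 - K1.conj().T)
        J = np.outer(d, d)
    K2 = np.zeros((norb, norb))
    K2[:nocc, nocc:] = t1
    K2[nocc:, :nocc] = -t1.T
    return LUCJParameters(K1=K1, Jaa=J.copy(), Jab=J.copy(),
                          K2=K2.astype(complex), n_occ=nocc)


def heavy_hex_mask(params: LUCJParameters) -> LUCJParameters:
    """Optional qubit-connectivity truncation: same-spin couplings limited
    to chain neighbours, opposite-spin to like orbitals."""
    n = params.norb
    near = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) <= 1
    return LUCJParameters(K1=params.K1, Jaa=params.Jaa * near,
                          Jab=params.Jab * np.eye(n), K2=params.K2,
                          n_occ=params.n_occ)


# ---------------------------------------------------------------------------
# exact sector simulation
# ---------------------------------------------------------------------------


def _string_op(K: np.ndarray, masks: np.ndarray, norb: int) -> np.ndarray:
    """Dense matrix of sum_pq K[pq] a+_p a_q in the half-string basis."""
    off, ent = _single_links(masks, masks, norb)
    n = len(masks)
    rows = []
    cols = []
    vals = []
    for i in range(n):
        for a in range(off[i], off[i + 1]):
            rows.append(ent[a, 2])
            cols.append(i)
            vals.append(ent[a, 3] * K[ent[a, 0], ent[a, 1]])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).toarray()


def simulate_lucj_state(params: LUCJParameters, n_alpha: int,
                        memory_cap: float = 1e7):
    """Exact LUCJ statevector over the (n_alpha, n_alpha) sector.

    Returns (C, masks): complex amplitudes C[Ia, Ib] and the half-string
    basis.  Norm is 1 to machine precision (all factors unitary).
    """
    norb = params.norb
    masks = make_strings(norb, n_alpha)
    n = len(masks)
    if n * n > memory_cap:
        raise MemoryError(
            f"sector dimension {n}^2 exceeds the memory cap {memory_cap:g}; "
            "use pre-drawn sample files instead of exact simulation")
    rhf_mask = (1 << n_alpha) - 1
    i0 = int(np.searchsorted(masks, rhf_mask))
    C = np.zeros((n, n), dtype=complex)
    C[i0, i0] = 1.0
    occ = occ_array(masks, norb)

    def one_body(Kmat, C):
        U = sla.expm(_string_op(Kmat, masks, norb))
        return U @ C @ U.T

    # exp(-K1)
    C = one_body(-params.K1, C)
    # diagonal Jastrow phase exp(i x^T J x)
    qa = np.einsum("ip,pq,iq->i", occ, params.Jaa, occ)
    cross = occ @ params.Jab @ occ.T
    phase = qa[:, None] + qa[None, :] + 2.0 * cross
    C = C * np.exp(1j * phase)
    # exp(K1), exp(-K2)
    C = one_body(params.K1, C)
    C = one_body(-params.K2, C)
    nrm = np.linalg.norm(C)
    if abs(nrm - 1.0) > 1e-8:
        raise RuntimeError(f"simulated state norm deviates: {nrm}")
    return C / nrm, masks


def sample_bitstrings(state: np.ndarray, masks: np.ndarray, shots: int,
                      seed: int, n_orb: int) -> SampleSet:
    """Multinomial draw from |<x|Phi>|^2."""
    if shots <= 0:
        raise ValueError("shots must be positive")
    p = np.abs(np.asarray(state)) ** 2
    p = (p / p.sum()).ravel()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(shots, p)
    nz = np.nonzero(counts)[0]
    n = len(masks)
    ia, ib = np.divmod(nz, n)
    out = SampleSet(alpha=masks[ia], beta=masks[ib], counts=counts[nz],
                    n_orb=n_orb, shots=shots, provenance="noiseless",
                    seed=seed)
    # sector sampling conserves particle number and spin-z by construction
    n_occ = int(np.bitwise_count(np.uint64(masks[0])))
    assert np.all(out.symmetry_ok(n_occ, n_occ))
    return out


def inject_noise(samples: SampleSet, p_flip: float, seed: int) -> SampleSet:
    """Independent bit flips with probability p_flip on every bit of every
    shot (classical stand-in for hardware noise breaking particle number
    and spin-z)."""
    if not 0.0 <= p_flip <= 1.0:
        raise ValueError("p_flip must be in [0, 1]")
    if p_flip == 0.0:
        return samples
    rng = np.random.default_rng(seed)
    n = samples.n_orb
    a = np.repeat(samples.alpha, samples.counts)
    b = np.repeat(samples.beta, samples.counts)
    bitpos = np.arange(n, dtype=np.int64)
    flips_a = rng.random((len(a), n)) < p_flip
    flips_b = rng.random((len(b), n)) < p_flip
    a = a ^ (flips_a.astype(np.int64) << bitpos).sum(axis=1)
    b = b ^ (flips_b.astype(np.int64) << bitpos).sum(axis=1)
    key = a * (1 << n) + b
    uniq, inv, cnt = np.unique(key, return_inverse=True, return_counts=True)
    ua = uniq >> n
    ub = uniq & ((1 << n) - 1)
    return SampleSet(alpha=ua, beta=ub, counts=cnt, n_orb=n,
                     shots=samples.shots, provenance=f"noisy({p_flip})",
                     seed=seed)
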