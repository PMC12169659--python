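"""Determinant-string CI machinery.

The Hamiltonian acts on CI coefficient matrices C[Ia, Ib] indexed by
alpha/beta occupation strings (bitmasks, orbital 0 = lowest bit).  The same
engine serves the full CAS sector and any spin-inversion-closed subspace
S = U x U spanned by a set U of half-strings: matrix elements between
subspace determinants are full-space Slater-Condon values, implemented by
composing single-excitation generators E_pq through intermediate strings
that may lie outside U (no renormalization).

sigma = A_alpha C + C A_beta^T + sum_{pq,rs} (pq|rs) E^a_pq (E^b_rs C)

where A is the exact one-spin Hamiltonian (sparse) and the mixed spin-spin
term is evaluated by gather / GEMM / scatter over single-excitation link
tables, blocked to bound memory.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.sparse as sp
from numba import njit


def make_strings(norb: int, nocc: int) -> np.ndarray:
    """All nocc-electron occupation bitmasks over norb orbitals, ascending."""
    if not 0 <= nocc <= norb:
        raise ValueError("invalid electron count")
    masks = [sum(1 << p for p in c) for c in combinations(range(norb), nocc)]
    return np.array(sorted(masks), dtype=np.int64)


def occ_array(masks: np.ndarray, norb: int) -> np.ndarray:
    """(nstr, norb) 0/1 occupation matrix."""
    return ((masks[:, None] >> np.arange(norb)[None, :]) & 1).astype(np.float64)


@njit(cache=True)
def _popcount_below(mask, p):
    m = mask & ((1 << p) - 1)
    c = 0
    while m:
        m &= m - 1
        c += 1
    return c


@njit(cache=True)
def _single_links(src, dst, norb):
    """Link table for E_pq = a+_p a_q from string set src into set dst.

    Returns (offsets, entries) with entries rows (p, q, jdst, sign);
    excitations whose target is not in dst are dropped.
    """
    ns = len(src)
    cnt = np.zeros(ns + 1, dtype=np.int64)
    # first pass: count
    for i in range(ns):
        I = src[i]
        c = 0
        for q in range(norb):
            if not (I >> q) & 1:
                continue
            for p in range(norb):
                if p != q and (I >> p) & 1:
                    continue
                J = (I ^ (1 << q)) | (1 << p)
                lo, hi = 0, len(dst)
                while lo < hi:
                    mid = (lo + hi) // 2
                    if dst[mid] < J:
                        lo = mid + 1
                    else:
                        hi = mid
                if lo < len(dst) and dst[lo] == J:
                    c += 1
        cnt[i + 1] = c
    offsets = np.zeros(ns + 1, dtype=np.int64)
    for i in range(ns):
        offsets[i + 1] = offsets[i] + cnt[i + 1]
    entries = np.zeros((offsets[ns], 4), dtype=np.int32)
    for i in range(ns):
        I = src[i]
        k = offsets[i]
        for q in range(norb):
            if not (I >> q) & 1:
                continue
            for p in range(norb):
                if p != q and (I >> p) & 1:
                    continue
                Imq = I ^ (1 << q)
                J = Imq | (1 << p)
                lo, hi = 0, len(dst)
                while lo < hi:
                    mid = (lo + hi) // 2
                    if dst[mid] < J:
                        lo = mid + 1
                    else:
                        hi = mid
                if lo < len(dst) and dst[lo] == J:
                    sgn = 1
                    if (_popcount_below(I, q) + _popcount_below(Imq, p)) & 1:
                        sgn = -1
                    entries[k, 0] = p
                    entries[k, 1] = q
                    entries[k, 2] = lo
                    entries[k, 3] = sgn
                    k += 1
    return offsets, entries


def expand_singles(masks: np.ndarray, norb: int) -> np.ndarray:
    """Union of masks with every single-excitation image (sorted)."""
    out = set(int(m) for m in masks)
    for m in masks:
        m = int(m)
        for q in range(norb):
            if not (m >> q) & 1:
                continue
            for p in range(norb):
                if (m >> p) & 1:
                    continue
                out.add((m ^ (1 << q)) | (1 << p))
    return np.array(sorted(out), dtype=np.int64)


@njit(cache=True)
def _accumulate_spin_ham(off_ue, ent_ue, off_eu, ent_eu, off_uu, ent_uu,
                         htilde, g, nu):
    """COO triplets of the exact one-spin Hamiltonian over string set U."""
    nterms = 0
    for i in range(nu):
        for a in range(off_ue[i], off_ue[i + 1]):
            k = ent_ue[a, 2]
            nterms += off_eu[k + 1] - off_eu[k]
    nterms += off_uu[nu]
    rows = np.zeros(nterms, dtype=np.int64)
    cols = np.zeros(nterms, dtype=np.int64)
    vals = np.zeros(nterms)
    n = 0
    for i in range(nu):
        # 1/2 (pq|rs) E_pq E_rs  via intermediate strings
        for a in range(off_ue[i], off_ue[i + 1]):
            r = ent_ue[a, 0]
            s = ent_ue[a, 1]
            k = ent_ue[a, 2]
            s1 = ent_ue[a, 3]
            for b in range(off_eu[k], off_eu[k + 1]):
                p = ent_eu[b, 0]
                q = ent_eu[b, 1]
                j = ent_eu[b, 2]
                s2 = ent_eu[b, 3]
                rows[n] = j
                cols[n] = i
                vals[n] = 0.5 * s1 * s2 * g[p, q, r, s]
                n += 1
        # htilde_pq E_pq  (includes the -1/2 delta reordering term)
        for a in range(off_uu[i], off_uu[i + 1]):
            p = ent_uu[a, 0]
            q = ent_uu[a, 1]
            j = ent_uu[a, 2]
            rows[n] = j
            cols[n] = i
            vals[n] = ent_uu[a, 3] * htilde[p, q]
            n += 1
    return rows, cols, vals


@njit(cache=True)
def _gather_t(C, off, ent, norb, ia0, ia1, t):
    """t[rs, ia-ia0, Jb] = sum_Ib <Jb|E_rs|Ib> C[ia, Ib] (beta excitations).

    t is a caller-owned buffer of shape (norb^2, >=ia1-ia0, nb)."""
    nb = C.shape[1]
    B = ia1 - ia0
    t[:, :B, :] = 0.0
    for ib in range(nb):
        for a in range(off[ib], off[ib + 1]):
            rs = ent[a, 0] * norb + ent[a, 1]
            jb = ent[a, 2]
            sgn = ent[a, 3]
            for ia in range(B):
                t[rs, ia, jb] += sgn * C[ia0 + ia, ib]


@njit(cache=True)
def _scatter_u(sigma, u, off, ent, norb, ia0, ia1):
    """sigma[Ja, :] += sum_pq <Ja|E_pq|Ia> u[pq, Ia-ia0, :]."""
    nb = sigma.shape[1]
    for ia in range(ia0, ia1):
        for a in range(off[ia], off[ia + 1]):
            pq = ent[a, 0] * norb + ent[a, 1]
            ja = ent[a, 2]
            sgn = ent[a, 3]
            if sgn == 1:
                for jb in range(nb):
                    sigma[ja, jb] += u[pq, ia - ia0, jb]
            else:
                for jb in range(nb):
                    sigma[ja, jb] -= u[pq, ia - ia0, jb]


@njit(cache=True)
def _rdm1_spin(C, off, ent, norb, alpha):
    """Spin-resolved 1-RDM gamma[p,q] = <C| E_pq |C> for one spin."""
    gamma = np.zeros((norb, norb))
    na, nb = C.shape
    if alpha:
        for ia in range(na):
            for a in range(off[ia], off[ia + 1]):
                p, q, ja, sgn = ent[a, 0], ent[a, 1], ent[a, 2], ent[a, 3]
                acc = 0.0
                for ib in range(nb):
                    acc += C[ja, ib] * C[ia, ib]
                gamma[p, q] += sgn * acc
    else:
        for ib in range(nb):
            for a in range(off[ib], off[ib + 1]):
                p, q, jb, sgn = ent[a, 0], ent[a, 1], ent[a, 2], ent[a, 3]
                acc = 0.0
                for ia in range(na):
                    acc += C[ia, jb] * C[ia, ib]
                gamma[p, q] += sgn * acc
    return gamma


class CIEngine:
    """Hamiltonian action over S = U_a x U_b (same string set both spins)."""

    def __init__(self, masks: np.ndarray, norb: int, nocc: int,
                 max_block_doubles: float = 6.0e7):
        self.masks = np.asarray(masks, dtype=np.int64)
        self.norb = norb
        self.nocc = nocc
        self.n_str = len(self.masks)
        self.dim = self.n_str ** 2
        self.off, self.ent = _single_links(self.masks, self.masks, norb)
        self._ext = expand_singles(self.masks, norb)
        self._off_ue, self._ent_ue = _single_links(self.masks, self._ext, norb)
        self._off_eu, self._ent_eu = _single_links(self._ext, self.masks, norb)
        self.max_block_doubles = max_block_doubles
        self._h = None
        self._g = None
        self._A = None
        self._diag = None
        self._tbuf = None
        self._ubuf = None

    def set_integrals(self, h1: np.ndarray, g: np.ndarray):
        """(Re)define h1/g (Hartree); rebuilds the one-spin sparse part."""
        self._h = np.asarray(h1, float)
        self._g = np.ascontiguousarray(g, dtype=float)
        htilde = self._h - 0.5 * np.einsum("prrs->ps", self._g)
        rows, cols, vals = _accumulate_spin_ham(
            self._off_ue, self._ent_ue, self._off_eu, self._ent_eu,
            self.off, self.ent, htilde, self._g, self.n_str)
        A = sp.coo_matrix((vals, (rows, cols)),
                          shape=(self.n_str, self.n_str)).tocsr()
        A.sum_duplicates()
        self._A = A
        self._g2 = np.ascontiguousarray(
            self._g.reshape(self.norb ** 2, self.norb ** 2))
        self._diag = None

    def diagonal(self) -> np.ndarray:
        """Diagonal <x|H|x> over the subspace, shape (n_str, n_str)."""
        if self._diag is None:
            dA = self._A.diagonal()
            O = occ_array(self.masks, self.norb)
            M = np.einsum("ppqq->pq", self._g)
            cross = O @ M @ O.T
            self._diag = dA[:, None] + dA[None, :] + cross
        return self._diag

    def matvec(self, C: np.ndarray) -> np.ndarray:
        """sigma = H C with C shaped (n_str, n_str)."""
        n = self.n_str
        K2 = self.norb ** 2
        sigma = self._A @ C + C @ self._A.T
        # mixed alpha-beta coulomb term, blocked over alpha rows
        B = max(1, min(n, int(self.max_block_doubles / (K2 * n))))
        if self._tbuf is None or self._tbuf.shape[1] < B \
                or self._tbuf.shape[2] != n:
            self._tbuf = np.empty((K2, B, n))
            self._ubuf = np.empty((K2, B * n))
        for ia0 in range(0, n, B):
            ia1 = min(n, ia0 + B)
            _gather_t(C, self.off, self.ent, self.norb, ia0, ia1,
                      self._tbuf)
            t2d = self._tbuf[:, :ia1 - ia0, :].reshape(K2, -1)
            u = np.matmul(self._g2, t2d,
                          out=self._ubuf[:, :t2d.shape[1]])
            _scatter_u(sigma, u.reshape(K2, ia1 - ia0, n),
                       self.off, self.ent, self.norb, ia0, ia1)
        return sigma

    def rdm1_spin(self, C: np.ndarray):
        ga = _rdm1_spin(C, self.off, self.ent, self.norb, True)
        gb = _rdm1_spin(C, self.off, self.ent, self.norb, False)
        return ga, gb

    def energy(self, C: np.ndarray) -> float:
        return float(np.sum(C * self.matvec(C)))


def davidson(matvec, diag, x0, tol=1e-8, max_space=20, max_iter=200):
    """Lowest eigenpair of a symmetric operator; diagonal preconditioner.

    x0 and all internal vectors are 1-D of length n.  Returns
    (eval, evec, n_iter, converged).
    """
    n = diag.size
    V = np.empty((max_space, n))
    W = np.empty((max_space, n))
    x = x0 / np.linalg.norm(x0)
    V[0] = x
    W[0] = matvec(x)
    m = 1
    theta = float(x @ W[0])
    evec = x.copy()
    for it in range(max_iter):
        H = V[:m] @ W[:m].T
        H = 0.5 * (H + H.T)
        w, U = np.linalg.eigh(H)
        theta = w[0]
        y = U[:, 0]
        evec = y @ V[:m]
        r = y @ W[:m] - theta * evec
        rnorm = np.linalg.norm(r)
        if rnorm < tol:
            return theta, evec, it, True
        # precondition
        denom = diag - theta
        denom[np.abs(denom) < 1e-8] = 1e-8
        d = r / denom
        # orthogonalize against V
        for _ in range(2):
            d -= (V[:m] @ d) @ V[:m]
        dn = np.linalg.norm(d)
        if dn < 1e-12 or m == max_space:
            # restart from current best
            V[0] = evec / np.linalg.norm(evec)
            W[0] = matvec(V[0])
            m = 1
            if dn < 1e-12:
                continue
            d -= (V[:m] @ d) @ V[:m]
            dn = np.linalg.norm(d)
            if dn < 1e-12:
                return theta, evec, it, True
        V[m] = d / dn
        W[m] = matvec(V[m])
        m += 1
    return theta, evec, max_iter, False


def predictor_vector(engine: CIEngine, max_strings: int = 400) -> np.ndarray:
    """Cheap Davidson start: ground state of the sub-block spanned by the
    half-strings with the lowest one-spin diagonal energies, embedded in
    the full coefficient matrix."""
    dA = engine._A.diagonal()
    order = np.argsort(dA)[:max_strings]
    sel = np.sort(order)
    sub = CIEngine(engine.masks[sel], engine.norb, engine.nocc)
    sub.set_integrals(engine._h, engine._g)
    _, Csub = solve_ground_state(sub, tol=1e-6)
    pos = np.searchsorted(engine.masks, sub.masks)
    C0 = np.zeros((engine.n_str, engine.n_str))
    C0[np.ix_(pos, pos)] = Csub
    return C0.ravel()


def solve_ground_state(engine: CIEngine, c0=None, tol=1e-8):
    """Davidson ground state of the engine's current Hamiltonian."""
    n = engine.n_str
    diag = engine.diagonal().ravel()
    if c0 is None:
        if n > 600:
            c0 = predictor_vector(engine)
        else:
            c0 = np.zeros(n * n)
            c0[int(np.argmin(diag))] = 1.0
    else:
        c0 = c0.ravel()

    def mv(x):
        return engine.matvec(x.reshape(n, n)).ravel()

    # cap workspace memory for multi-million-determinant sectors
    max_space = 20 if n * n <= 1_000_000 else 12
    e, v, nit, conv = davidson(mv, diag.copy(), c0, tol=tol,
                               max_space=max_space)
    if not conv:
        raise RuntimeError(f"Davidson failed to converge ({nit} iterations)")
    C = v.reshape(n, n)
    return e, C / np.linalg.norm(C)
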