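"""Molecular integrals over contracted Gaussians (McMurchie-Davidson).

Cartesian integrals are generated by Hermite-Gaussian recursions in
numba-compiled kernels and transformed to the real solid-harmonic basis.
Provides overlap, kinetic, nuclear attraction, electron repulsion, and the
electrostatic potential operator at arbitrary points (the quantity the
polarizable-continuum solver needs on the cavity surface).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .basis import Shell, c2s_matrix, cart_components, n_basis

# ---------------------------------------------------------------------------
# flattened shell arrays for numba
# ---------------------------------------------------------------------------


def pack_shells(shells: list[Shell]):
    nsh = len(shells)
    l = np.array([s.l for s in shells], dtype=np.int64)
    nprim = np.array([len(s.exps) for s in shells], dtype=np.int64)
    pstart = np.zeros(nsh + 1, dtype=np.int64)
    pstart[1:] = np.cumsum(nprim)
    exps = np.concatenate([s.exps for s in shells])
    coefs = np.concatenate([s.coefs for s in shells])
    centers = np.array([s.center for s in shells])
    cart_off = np.array([s.cart_offset for s in shells], dtype=np.int64)
    ncart_tot = int(cart_off[-1] + (l[-1] + 1) * (l[-1] + 2) // 2)
    # cartesian component table, indexed by l
    comp_off = np.zeros(5, dtype=np.int64)
    comps = []
    for ll in range(4):
        c = cart_components(ll)
        comps.append(c)
        comp_off[ll + 1] = comp_off[ll] + len(c)
    comps = np.concatenate(comps)
    return (l, pstart, exps, coefs, centers, cart_off, ncart_tot,
            comps, comp_off)


def c2s_block(shells: list[Shell], ncart_tot: int) -> np.ndarray:
    """Block-diagonal cartesian->spherical transformation, (ncart, nsph)."""
    T = np.zeros((ncart_tot, n_basis(shells)))
    for s in shells:
        M = c2s_matrix(s.l)  # (nsph, ncart)
        T[s.cart_offset:s.cart_offset + s.n_cart,
          s.ao_offset:s.ao_offset + s.n_sph] = M.T
    return T


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _boys(mmax, T, F):
    """Fill F[0..mmax] with Boys functions F_m(T)."""
    if T < 1e-13:
        for m in range(mmax + 1):
            F[m] = 1.0 / (2 * m + 1)
        return
    if T < 35.0:
        # series for the highest order, then downward recursion
        m = mmax
        term = 1.0 / (2 * m + 1)
        s = term
        i = 1
        while True:
            term *= 2.0 * T / (2 * m + 2 * i + 1)
            s += term
            if term < 1e-17 * s or i > 200:
                break
            i += 1
        eT = np.exp(-T)
        F[mmax] = s * eT
        for k in range(mmax - 1, -1, -1):
            F[k] = (2.0 * T * F[k + 1] + eT) / (2 * k + 1)
    else:
        F[0] = 0.5 * np.sqrt(np.pi / T)
        eT = np.exp(-T) if T < 700 else 0.0
        for k in range(mmax):
            F[k + 1] = ((2 * k + 1) * F[k] - eT) / (2.0 * T)


@njit(cache=True)
def _fill_E(E, imax, jmax, PA, PB, oo2p):
    """Hermite expansion coefficients E[i,j,t] along one axis.

    E^{00}_0 = 1 convention; the Gaussian-product prefactor is applied by
    the caller.
    """
    E[:, :, :] = 0.0
    E[0, 0, 0] = 1.0
    for i in range(1, imax + 1):
        for t in range(i + 1):
            v = PA * E[i - 1, 0, t]
            if t > 0:
                v += oo2p * E[i - 1, 0, t - 1]
            if t + 1 <= i - 1:
                v += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = v
    for j in range(1, jmax + 1):
        for i in range(imax + 1):
            for t in range(i + j + 1):
                v = PB * E[i, j - 1, t]
                if t > 0:
                    v += oo2p * E[i, j - 1, t - 1]
                if t + 1 <= i + j - 1:
                    v += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = v


@njit(cache=True)
def _fill_R(R, L, alpha, X, Y, Z, F):
    """Hermite Coulomb integrals R[t,u,v] (n=0) for t+u+v <= L.

    R4[n,t,u,v] auxiliary recursion; F holds Boys values F_0..F_L of
    T = alpha*(X^2+Y^2+Z^2).
    """
    R4 = np.zeros((L + 1, L + 1, L + 1, L + 1))
    m2a = 1.0
    for n in range(L + 1):
        R4[n, 0, 0, 0] = m2a * F[n]
        m2a *= -2.0 * alpha
    for ntot in range(1, L + 1):
        for t in range(ntot + 1):
            for u in range(ntot - t + 1):
                v = ntot - t - u
                for n in range(L - ntot + 1):
                    if t > 0:
                        val = X * R4[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R4[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R4[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R4[n + 1, t, u - 2, v]
                    else:
                        val = Z * R4[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R4[n + 1, t, u, v - 2]
                    R4[n, t, u, v] = val
    for t in range(L + 1):
        for u in range(L - t + 1):
            for v in range(L - t - u + 1):
                R[t, u, v] = R4[0, t, u, v]


@njit(cache=True)
def _overlap_kinetic_cart(l, pstart, exps, coefs, centers, cart_off,
                          ncart, comps, comp_off):
    S = np.zeros((ncart, ncart))
    K = np.zeros((ncart, ncart))
    nsh = len(l)
    for ish in range(nsh):
        la = l[ish]
        A = centers[ish]
        nca = (la + 1) * (la + 2) // 2
        for jsh in range(ish + 1):
            lb = l[jsh]
            B = centers[jsh]
            ncb = (lb + 1) * (lb + 2) // 2
            AB2 = 0.0
            for d in range(3):
                AB2 += (A[d] - B[d]) ** 2
            sblk = np.zeros((nca, ncb))
            kblk = np.zeros((nca, ncb))
            Ex = np.zeros((la + 1, lb + 3, la + lb + 3))
            Ey = np.zeros((la + 1, lb + 3, la + lb + 3))
            Ez = np.zeros((la + 1, lb + 3, la + lb + 3))
            for ip in range(pstart[ish], pstart[ish + 1]):
                a = exps[ip]
                ca = coefs[ip]
                for jp in range(pstart[jsh], pstart[jsh + 1]):
                    b = exps[jp]
                    cb = coefs[jp]
                    p = a + b
                    oo2p = 0.5 / p
                    mu = a * b / p
                    pref = ca * cb * np.exp(-mu * AB2) * (np.pi / p) ** 1.5
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    _fill_E(Ex, la, lb + 2, Px - A[0], Px - B[0], oo2p)
                    _fill_E(Ey, la, lb + 2, Py - A[1], Py - B[1], oo2p)
                    _fill_E(Ez, la, lb + 2, Pz - A[2], Pz - B[2], oo2p)
                    for ic in range(nca):
                        ax = comps[comp_off[la] + ic, 0]
                        ay = comps[comp_off[la] + ic, 1]
                        az = comps[comp_off[la] + ic, 2]
                        for jc in range(ncb):
                            bx = comps[comp_off[lb] + jc, 0]
                            by = comps[comp_off[lb] + jc, 1]
                            bz = comps[comp_off[lb] + jc, 2]
                            sx = Ex[ax, bx, 0]
                            sy = Ey[ay, by, 0]
                            sz = Ez[az, bz, 0]
                            sblk[ic, jc] += pref * sx * sy * sz
                            # 1D kinetic factors
                            tx = -2.0 * b * b * Ex[ax, bx + 2, 0] \
                                + b * (2 * bx + 1) * sx
                            if bx > 1:
                                tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                            ty = -2.0 * b * b * Ey[ay, by + 2, 0] \
                                + b * (2 * by + 1) * sy
                            if by > 1:
                                ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                            tz = -2.0 * b * b * Ez[az, bz + 2, 0] \
                                + b * (2 * bz + 1) * sz
                            if bz > 1:
                                tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                            kblk[ic, jc] += pref * (tx * sy * sz
                                                    + sx * ty * sz
                                                    + sx * sy * tz)
            for ic in range(nca):
                for jc in range(ncb):
                    ia = cart_off[ish] + ic
                    jb = cart_off[jsh] + jc
                    S[ia, jb] = sblk[ic, jc]
                    S[jb, ia] = sblk[ic, jc]
                    K[ia, jb] = kblk[ic, jc]
                    K[jb, ia] = kblk[ic, jc]
    return S, K


@njit(cache=True)
def _potential_cart(l, pstart, exps, coefs, centers, cart_off, ncart,
                    comps, comp_off, points, charges):
    """V[k, i, j] = integral chi_i(r) chi_j(r) * charges[k] / |r - points[k]|.

    With charges = +1 this is the (positive) Coulomb kernel; the caller
    applies physical signs.  Nuclear attraction is obtained by summing over
    k with charges = Z_k and negating.
    """
    npts = len(points)
    V = np.zeros((npts, ncart, ncart))
    nsh = len(l)
    for ish in range(nsh):
        la = l[ish]
        A = centers[ish]
        nca = (la + 1) * (la + 2) // 2
        for jsh in range(ish + 1):
            lb = l[jsh]
            B = centers[jsh]
            ncb = (lb + 1) * (lb + 2) // 2
            L = la + lb
            AB2 = 0.0
            for d in range(3):
                AB2 += (A[d] - B[d]) ** 2
            Ex = np.zeros((la + 1, lb + 1, L + 1))
            Ey = np.zeros((la + 1, lb + 1, L + 1))
            Ez = np.zeros((la + 1, lb + 1, L + 1))
            R = np.zeros((L + 1, L + 1, L + 1))
            F = np.zeros(L + 1)
            blk = np.zeros((npts, nca, ncb))
            for ip in range(pstart[ish], pstart[ish + 1]):
                a = exps[ip]
                ca = coefs[ip]
                for jp in range(pstart[jsh], pstart[jsh + 1]):
                    b = exps[jp]
                    cb = coefs[jp]
                    p = a + b
                    oo2p = 0.5 / p
                    mu = a * b / p
                    pref = ca * cb * np.exp(-mu * AB2) * 2.0 * np.pi / p
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    _fill_E(Ex, la, lb, Px - A[0], Px - B[0], oo2p)
                    _fill_E(Ey, la, lb, Py - A[1], Py - B[1], oo2p)
                    _fill_E(Ez, la, lb, Pz - A[2], Pz - B[2], oo2p)
                    for k in range(npts):
                        X = Px - points[k, 0]
                        Y = Py - points[k, 1]
                        Z = Pz - points[k, 2]
                        T = p * (X * X + Y * Y + Z * Z)
                        _boys(L, T, F)
                        _fill_R(R, L, p, X, Y, Z, F)
                        q = charges[k] * pref
                        for ic in range(nca):
                            ax = comps[comp_off[la] + ic, 0]
                            ay = comps[comp_off[la] + ic, 1]
                            az = comps[comp_off[la] + ic, 2]
                            for jc in range(ncb):
                                bx = comps[comp_off[lb] + jc, 0]
                                by = comps[comp_off[lb] + jc, 1]
                                bz = comps[comp_off[lb] + jc, 2]
                                acc = 0.0
                                for t in range(ax + bx + 1):
                                    ext = Ex[ax, bx, t]
                                    if ext == 0.0:
                                        continue
                                    for u in range(ay + by + 1):
                                        eyu = Ey[ay, by, u]
                                        if eyu == 0.0:
                                            continue
                                        for v in range(az + bz + 1):
                                            ezv = Ez[az, bz, v]
                                            if ezv != 0.0:
                                                acc += ext * eyu * ezv \
                                                    * R[t, u, v]
                                blk[k, ic, jc] += q * acc
            for k in range(npts):
                for ic in range(nca):
                    for jc in range(ncb):
                        ia = cart_off[ish] + ic
                        jb = cart_off[jsh] + jc
                        V[k, ia, jb] = blk[k, ic, jc]
                        V[k, jb, ia] = blk[k, ic, jc]
    return V


@njit(cache=True)
def _eri_cart(l, pstart, exps, coefs, centers, cart_off, ncart,
              comps, comp_off):
    nsh = len(l)
    G = np.zeros((ncart, ncart, ncart, ncart))
    # shell pair list (i >= j)
    npair = nsh * (nsh + 1) // 2
    pair_i = np.zeros(npair, dtype=np.int64)
    pair_j = np.zeros(npair, dtype=np.int64)
    c = 0
    for i in range(nsh):
        for j in range(i + 1):
            pair_i[c] = i
            pair_j[c] = j
            c += 1
    maxl = 0
    for i in range(nsh):
        if l[i] > maxl:
            maxl = l[i]
    Lmax = 4 * maxl
    F = np.zeros(Lmax + 1)
    R = np.zeros((Lmax + 1, Lmax + 1, Lmax + 1))
    for ipair in range(npair):
        ish = pair_i[ipair]
        jsh = pair_j[ipair]
        la, lb = l[ish], l[jsh]
        A, B = centers[ish], centers[jsh]
        nca = (la + 1) * (la + 2) // 2
        ncb = (lb + 1) * (lb + 2) // 2
        AB2 = 0.0
        for d in range(3):
            AB2 += (A[d] - B[d]) ** 2
        npb = (pstart[ish + 1] - pstart[ish]) * (pstart[jsh + 1] - pstart[jsh])
        bEx = np.zeros((npb, la + 1, lb + 1, la + lb + 1))
        bEy = np.zeros((npb, la + 1, lb + 1, la + lb + 1))
        bEz = np.zeros((npb, la + 1, lb + 1, la + lb + 1))
        bP = np.zeros((npb, 3))
        bp = np.zeros(npb)
        bc = np.zeros(npb)
        nb = 0
        for ip in range(pstart[ish], pstart[ish + 1]):
            a = exps[ip]
            for jp in range(pstart[jsh], pstart[jsh + 1]):
                b = exps[jp]
                p = a + b
                mu = a * b / p
                bp[nb] = p
                bc[nb] = coefs[ip] * coefs[jp] * np.exp(-mu * AB2)
                for d in range(3):
                    bP[nb, d] = (a * A[d] + b * B[d]) / p
                _fill_E(bEx[nb], la, lb, bP[nb, 0] - A[0], bP[nb, 0] - B[0],
                        0.5 / p)
                _fill_E(bEy[nb], la, lb, bP[nb, 1] - A[1], bP[nb, 1] - B[1],
                        0.5 / p)
                _fill_E(bEz[nb], la, lb, bP[nb, 2] - A[2], bP[nb, 2] - B[2],
                        0.5 / p)
                nb += 1
        for jpair in range(ipair + 1):
            ksh = pair_i[jpair]
            lsh = pair_j[jpair]
            lc, ld = l[ksh], l[lsh]
            C, D = centers[ksh], centers[lsh]
            ncc = (lc + 1) * (lc + 2) // 2
            ncd = (ld + 1) * (ld + 2) // 2
            CD2 = 0.0
            for d in range(3):
                CD2 += (C[d] - D[d]) ** 2
            Lb = la + lb
            Lk = lc + ld
            L = Lb + Lk
            blk = np.zeros((nca, ncb, ncc, ncd))
            kEx = np.zeros((lc + 1, ld + 1, Lk + 1))
            kEy = np.zeros((lc + 1, ld + 1, Lk + 1))
            kEz = np.zeros((lc + 1, ld + 1, Lk + 1))
            for kp in range(pstart[ksh], pstart[ksh + 1]):
                ck = exps[kp]
                for lp in range(pstart[lsh], pstart[lsh + 1]):
                    cl = exps[lp]
                    q = ck + cl
                    muq = ck * cl / q
                    cq = coefs[kp] * coefs[lp] * np.exp(-muq * CD2)
                    Qx = (ck * C[0] + cl * D[0]) / q
                    Qy = (ck * C[1] + cl * D[1]) / q
                    Qz = (ck * C[2] + cl * D[2]) / q
                    _fill_E(kEx, lc, ld, Qx - C[0], Qx - D[0], 0.5 / q)
                    _fill_E(kEy, lc, ld, Qy - C[1], Qy - D[1], 0.5 / q)
                    _fill_E(kEz, lc, ld, Qz - C[2], Qz - D[2], 0.5 / q)
                    for ib in range(nb):
                        p = bp[ib]
                        alpha = p * q / (p + q)
                        X = bP[ib, 0] - Qx
                        Y = bP[ib, 1] - Qy
                        Z = bP[ib, 2] - Qz
                        T = alpha * (X * X + Y * Y + Z * Z)
                        _boys(L, T, F)
                        _fill_R(R, L, alpha, X, Y, Z, F)
                        pref = bc[ib] * cq * 2.0 * np.pi ** 2.5 \
                            / (p * q * np.sqrt(p + q))
                        for ic in range(nca):
                            ax = comps[comp_off[la] + ic, 0]
                            ay = comps[comp_off[la] + ic, 1]
                            az = comps[comp_off[la] + ic, 2]
                            for jc in range(ncb):
                                bx = comps[comp_off[lb] + jc, 0]
                                by = comps[comp_off[lb] + jc, 1]
                                bz = comps[comp_off[lb] + jc, 2]
                                for kc in range(ncc):
                                    cx = comps[comp_off[lc] + kc, 0]
                                    cy = comps[comp_off[lc] + kc, 1]
                                    cz = comps[comp_off[lc] + kc, 2]
                                    for dc in range(ncd):
                                        dx = comps[comp_off[ld] + dc, 0]
                                        dy = comps[comp_off[ld] + dc, 1]
                                        dz = comps[comp_off[ld] + dc, 2]
                                        acc = 0.0
                                        for t in range(ax + bx + 1):
                                            e1 = bEx[ib, ax, bx, t]
                                            if e1 == 0.0:
                                                continue
                                            for u in range(ay + by + 1):
                                                e2 = e1 * bEy[ib, ay, by, u]
                                                if e2 == 0.0:
                                                    continue
                                                for v in range(az + bz + 1):
                                                    e3 = e2 * bEz[ib, az,
                                                                  bz, v]
                                                    if e3 == 0.0:
                                                        continue
                                                    # ket hermite sum
                                                    acck = 0.0
                                                    sgn_t = 1.0
                                                    for tt in range(
                                                            cx + dx + 1):
                                                        k1 = kEx[cx, dx, tt] \
                                                            * sgn_t
                                                        sgn_t = -sgn_t
                                                        if k1 == 0.0:
                                                            continue
                                                        sgn_u = 1.0
                                                        for uu in range(
                                                                cy + dy + 1):
                                                            k2 = k1 * kEy[
                                                                cy, dy, uu] \
                                                                * sgn_u
                                                            sgn_u = -sgn_u
                                                            if k2 == 0.0:
                                                                continue
                                                            sgn_v = 1.0
                                                            for vv in range(
                                                                    cz + dz
                                                                    + 1):
                                                                k3 = k2 * kEz[
                                                                    cz, dz,
                                                                    vv] * \
                                                                    sgn_v
                                                                sgn_v = -sgn_v
                                                                if k3 != 0.0:
                                                                    acck += \
                                                                        k3 * R[
                                                                        t + tt,
                                                                        u + uu,
                                                                        v + vv]
                                                    acc += e3 * acck
                                        blk[ic, jc, kc, dc] += pref * acc
            oa, ob = cart_off[ish], cart_off[jsh]
            oc, od = cart_off[ksh], cart_off[lsh]
            for ic in range(nca):
                for jc in range(ncb):
                    for kc in range(ncc):
                        for dc in range(ncd):
                            v = blk[ic, jc, kc, dc]
                            i1, j1 = oa + ic, ob + jc
                            k1, l1 = oc + kc, od + dc
                            G[i1, j1, k1, l1] = v
                            G[j1, i1, k1, l1] = v
                            G[i1, j1, l1, k1] = v
                            G[j1, i1, l1, k1] = v
                            G[k1, l1, i1, j1] = v
                            G[l1, k1, i1, j1] = v
                            G[k1, l1, j1, i1] = v
                            G[l1, k1, j1, i1] = v
    return G


# ---------------------------------------------------------------------------
# public API (spherical basis)
# ---------------------------------------------------------------------------


def overlap_kinetic(shells):
    pk = pack_shells(shells)
    S, K = _overlap_kinetic_cart(*pk[:6], pk[6], pk[7], pk[8])
    T = c2s_block(shells, pk[6])
    return T.T @ S @ T, T.T @ K @ T


def potential_integrals(shells, points, charges=None):
    """Coulomb-kernel matrices 1/|r - s_k| for each point, spherical basis.

    Returns array (npts, nbf, nbf); positive-kernel convention (multiply by
    -1 for the interaction of the electron density with a positive charge).
    """
    points = np.ascontiguousarray(np.atleast_2d(points), dtype=float)
    if charges is None:
        charges = np.ones(len(points))
    pk = pack_shells(shells)
    V = _potential_cart(*pk[:6], pk[6], pk[7], pk[8],
                        points, np.asarray(charges, float))
    T = c2s_block(shells, pk[6])
    return np.einsum("ci,kcd,dj->kij", T, V, T, optimize=True)


def nuclear_attraction(shells, charges, positions):
    """Nuclear-attraction matrix (negative-definite-ish) -sum_A Z_A/|r-R_A|."""
    V = potential_integrals(shells, positions, charges)
    return -V.sum(axis=0)


def eri(shells):
    """Full (ij|kl) tensor in the spherical-harmonic basis (chemists')."""
    pk = pack_shells(shells)
    G = _eri_cart(*pk[:6], pk[6], pk[7], pk[8])
    T = c2s_block(shells, pk[6])
    n = T.shape[1]
    # four identical half-transforms; the final index order [l,k,j,i]
    # coincides with [i,j,k,l] because (ij|kl) = (kl|ij) = (ji|lk)
    for _ in range(4):
        G = np.tensordot(T, G, axes=(0, 3))
    return np.ascontiguousarray(G.reshape(n, n, n, n))
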