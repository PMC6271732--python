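"""Molecular integrals over contracted cartesian Gaussians.

McMurchie–Davidson scheme throughout: Hermite expansion coefficients E_t
for overlap-type products, Hermite Coulomb repeated-derivative tensor
R_tuv on top of the Boys function for anything with 1/r.  The hot loops
are numba-compiled; wrappers accept a :class:`~nearsight.qm.basis.BasisSet`.

Supported angular momenta: s, p, d (l <= 2), which covers the shipped
basis sets.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import CART_COMPONENTS, BasisSet, component_norm_ratio

_LMAX = 2
_MMAX = 4 * _LMAX + 2  # highest Boys order ever needed (ERI: sum of 4 l's)

# flat cartesian component tables, padded to 6 entries
_COMP = np.zeros((_LMAX + 1, 6, 3), dtype=np.int64)
_CNRM = np.zeros((_LMAX + 1, 6))
_NCOMP = np.zeros(_LMAX + 1, dtype=np.int64)
for _l, _comps in CART_COMPONENTS.items():
    _NCOMP[_l] = len(_comps)
    for _i, (_lx, _ly, _lz) in enumerate(_comps):
        _COMP[_l, _i] = (_lx, _ly, _lz)
        _CNRM[_l, _i] = component_norm_ratio(_lx, _ly, _lz)


@njit
def _boys(mmax, T, out):
    """Fill out[0..mmax] with Boys functions F_m(T)."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T < 35.0:
        # series for the top order, then stable downward recursion
        et = math.exp(-T)
        s = 0.0
        term = 1.0 / (2 * mmax + 1)
        k = 0
        while True:
            s += term
            k += 1
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            if term < 1e-17 * s or k > 400:
                break
        out[mmax] = et * s
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + et) / (2 * m + 1)
    else:
        et = math.exp(-T)
        out[0] = 0.5 * math.sqrt(math.pi / T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - et) / (2.0 * T)


@njit
def _Ecoef(i, j, t, Qx, a, b):
    """Hermite expansion coefficient E_t^{ij} for a 1D Gaussian product."""
    p = a + b
    mu = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == 0 and j == 0 and t == 0:
        return math.exp(-mu * Qx * Qx)
    if j == 0:
        return (
            _Ecoef(i - 1, j, t - 1, Qx, a, b) / (2.0 * p)
            - (mu * Qx / a) * _Ecoef(i - 1, j, t, Qx, a, b)
            + (t + 1) * _Ecoef(i - 1, j, t + 1, Qx, a, b)
        )
    return (
        _Ecoef(i, j - 1, t - 1, Qx, a, b) / (2.0 * p)
        + (mu * Qx / b) * _Ecoef(i, j - 1, t, Qx, a, b)
        + (t + 1) * _Ecoef(i, j - 1, t + 1, Qx, a, b)
    )


@njit
def _Rtuv(t, u, v, n, p, X, Y, Z, fb):
    """Hermite Coulomb tensor R^n_{tuv}; fb holds Boys values F_m(p*R2)."""
    if t < 0 or u < 0 or v < 0:
        return 0.0
    if t == 0 and u == 0 and v == 0:
        return (-2.0 * p) ** n * fb[n]
    if t > 0:
        val = X * _Rtuv(t - 1, u, v, n + 1, p, X, Y, Z, fb)
        if t > 1:
            val += (t - 1) * _Rtuv(t - 2, u, v, n + 1, p, X, Y, Z, fb)
        return val
    if u > 0:
        val = Y * _Rtuv(t, u - 1, v, n + 1, p, X, Y, Z, fb)
        if u > 1:
            val += (u - 1) * _Rtuv(t, u - 2, v, n + 1, p, X, Y, Z, fb)
        return val
    val = Z * _Rtuv(t, u, v - 1, n + 1, p, X, Y, Z, fb)
    if v > 1:
        val += (v - 1) * _Rtuv(t, u, v - 2, n + 1, p, X, Y, Z, fb)
    return val


@njit
def _prim_overlap(la, lb, a, b, A, B):
    """(6,6) overlap block of one primitive pair, (l,0,0)-normalized units."""
    out = np.zeros((6, 6))
    p = a + b
    pref = (math.pi / p) ** 1.5
    for ca in range(_NCOMP[la]):
        for cb in range(_NCOMP[lb]):
            val = 1.0
            for k in range(3):
                val *= _Ecoef(_COMP[la, ca, k], _COMP[lb, cb, k], 0, A[k] - B[k], a, b)
            out[ca, cb] = pref * val * _CNRM[la, ca] * _CNRM[lb, cb]
    return out


@njit
def _prim_kinetic(la, lb, a, b, A, B):
    """Kinetic block via l2-raised/lowered overlaps."""
    out = np.zeros((6, 6))
    p = a + b
    pref = (math.pi / p) ** 1.5
    for ca in range(_NCOMP[la]):
        for cb in range(_NCOMP[lb]):
            lb_x = _COMP[lb, cb, 0]
            lb_y = _COMP[lb, cb, 1]
            lb_z = _COMP[lb, cb, 2]
            s = np.zeros(7)  # base, +2x, +2y, +2z, -2x, -2y, -2z
            for idx in range(7):
                dx = dy = dz = 0
                if idx == 1:
                    dx = 2
                elif idx == 2:
                    dy = 2
                elif idx == 3:
                    dz = 2
                elif idx == 4:
                    dx = -2
                elif idx == 5:
                    dy = -2
                elif idx == 6:
                    dz = -2
                if lb_x + dx < 0 or lb_y + dy < 0 or lb_z + dz < 0:
                    s[idx] = 0.0
                    continue
                val = 1.0
                lbs = (lb_x + dx, lb_y + dy, lb_z + dz)
                for k in range(3):
                    val *= _Ecoef(_COMP[la, ca, k], lbs[k], 0, A[k] - B[k], a, b)
                s[idx] = pref * val
            lsum = lb_x + lb_y + lb_z
            t = b * (2 * lsum + 3) * s[0]
            t -= 2.0 * b * b * (s[1] + s[2] + s[3])
            t -= 0.5 * (lb_x * (lb_x - 1) * s[4] + lb_y * (lb_y - 1) * s[5] + lb_z * (lb_z - 1) * s[6])
            out[ca, cb] = t * _CNRM[la, ca] * _CNRM[lb, cb]
    return out


@njit
def _prim_nuclear(la, lb, a, b, A, B, charges, coords):
    """Nuclear-attraction block, summed over all nuclei (negative sign included)."""
    out = np.zeros((6, 6))
    p = a + b
    P = (a * A + b * B) / p
    fb = np.zeros(_MMAX + 1)
    lmax = la + lb
    Et = np.zeros((6, 6, 3, 2 * _LMAX + 1))
    for ca in range(_NCOMP[la]):
        for cb in range(_NCOMP[lb]):
            for k in range(3):
                for t in range(_COMP[la, ca, k] + _COMP[lb, cb, k] + 1):
                    Et[ca, cb, k, t] = _Ecoef(_COMP[la, ca, k], _COMP[lb, cb, k], t, A[k] - B[k], a, b)
    for ia in range(charges.shape[0]):
        C = coords[ia]
        X = P[0] - C[0]
        Y = P[1] - C[1]
        Z = P[2] - C[2]
        R2 = X * X + Y * Y + Z * Z
        _boys(lmax, p * R2, fb)
        for ca in range(_NCOMP[la]):
            for cb in range(_NCOMP[lb]):
                acc = 0.0
                for t in range(_COMP[la, ca, 0] + _COMP[lb, cb, 0] + 1):
                    for u in range(_COMP[la, ca, 1] + _COMP[lb, cb, 1] + 1):
                        for v in range(_COMP[la, ca, 2] + _COMP[lb, cb, 2] + 1):
                            e = Et[ca, cb, 0, t] * Et[ca, cb, 1, u] * Et[ca, cb, 2, v]
                            if e != 0.0:
                                acc += e * _Rtuv(t, u, v, 0, p, X, Y, Z, fb)
                out[ca, cb] -= charges[ia] * 2.0 * math.pi / p * acc * _CNRM[la, ca] * _CNRM[lb, cb]
    return out


@njit
def _one_electron(ls, nprim, ptr, exps, coefs, centers, charges, coords, kind):
    """Assemble S (kind=0), T (kind=1) or V_nuc (kind=2) over all shells."""
    nsh = ls.shape[0]
    nao_of = np.zeros(nsh + 1, dtype=np.int64)
    for i in range(nsh):
        nao_of[i + 1] = nao_of[i] + _NCOMP[ls[i]]
    nao = nao_of[nsh]
    M = np.zeros((nao, nao))
    for i in range(nsh):
        for j in range(i + 1):
            block = np.zeros((6, 6))
            for pi in range(nprim[i]):
                a = exps[ptr[i] + pi]
                ca = coefs[ptr[i] + pi]
                for pj in range(nprim[j]):
                    b = exps[ptr[j] + pj]
                    cb = coefs[ptr[j] + pj]
                    if kind == 0:
                        blk = _prim_overlap(ls[i], ls[j], a, b, centers[i], centers[j])
                    elif kind == 1:
                        blk = _prim_kinetic(ls[i], ls[j], a, b, centers[i], centers[j])
                    else:
                        blk = _prim_nuclear(ls[i], ls[j], a, b, centers[i], centers[j], charges, coords)
                    block += ca * cb * blk
            for ci in range(_NCOMP[ls[i]]):
                for cj in range(_NCOMP[ls[j]]):
                    M[nao_of[i] + ci, nao_of[j] + cj] = block[ci, cj]
                    M[nao_of[j] + cj, nao_of[i] + ci] = block[ci, cj]
    return M


@njit
def _eri_quartet(la, lb, lc, ld, ea, eb, ec, ed, ca, cb, cc, cd, A, B, C, D, out):
    """Contracted ERI block (ab|cd) -> out[6,6,6,6] (chemists' notation)."""
    na, nb, nc, nd = _NCOMP[la], _NCOMP[lb], _NCOMP[lc], _NCOMP[ld]
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                for l in range(nd):
                    out[i, j, k, l] = 0.0
    fb = np.zeros(_MMAX + 1)
    lab = la + lb
    lcd = lc + ld
    ltot = lab + lcd
    for pa in range(ea.shape[0]):
        a = ea[pa]
        for pb in range(eb.shape[0]):
            b = eb[pb]
            p = a + b
            P = (a * A + b * B) / p
            cab = ca[pa] * cb[pb]
            # bra Hermite coefficients
            Eab = np.zeros((6, 6, 3, 2 * _LMAX + 1))
            for i in range(na):
                for j in range(nb):
                    for x in range(3):
                        for t in range(_COMP[la, i, x] + _COMP[lb, j, x] + 1):
                            Eab[i, j, x, t] = _Ecoef(
                                _COMP[la, i, x], _COMP[lb, j, x], t, A[x] - B[x], a, b
                            )
            for pc in range(ec.shape[0]):
                c = ec[pc]
                for pd in range(ed.shape[0]):
                    d = ed[pd]
                    q = c + d
                    Q = (c * C + d * D) / q
                    ccd = cc[pc] * cd[pd]
                    alpha = p * q / (p + q)
                    X = P[0] - Q[0]
                    Y = P[1] - Q[1]
                    Z = P[2] - Q[2]
                    R2 = X * X + Y * Y + Z * Z
                    _boys(ltot, alpha * R2, fb)
                    pref = 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q)) * cab * ccd
                    Ecd = np.zeros((6, 6, 3, 2 * _LMAX + 1))
                    for k in range(nc):
                        for l in range(nd):
                            for x in range(3):
                                for t in range(_COMP[lc, k, x] + _COMP[ld, l, x] + 1):
                                    Ecd[k, l, x, t] = _Ecoef(
                                        _COMP[lc, k, x], _COMP[ld, l, x], t, C[x] - D[x], c, d
                                    )
                    for i in range(na):
                        for j in range(nb):
                            for k in range(nc):
                                for l in range(nd):
                                    acc = 0.0
                                    for t in range(_COMP[la, i, 0] + _COMP[lb, j, 0] + 1):
                                        for u in range(_COMP[la, i, 1] + _COMP[lb, j, 1] + 1):
                                            for v in range(_COMP[la, i, 2] + _COMP[lb, j, 2] + 1):
                                                e1 = Eab[i, j, 0, t] * Eab[i, j, 1, u] * Eab[i, j, 2, v]
                                                if e1 == 0.0:
                                                    continue
                                                for tt in range(_COMP[lc, k, 0] + _COMP[ld, l, 0] + 1):
                                                    for uu in range(_COMP[lc, k, 1] + _COMP[ld, l, 1] + 1):
                                                        for vv in range(_COMP[lc, k, 2] + _COMP[ld, l, 2] + 1):
                                                            e2 = Ecd[k, l, 0, tt] * Ecd[k, l, 1, uu] * Ecd[k, l, 2, vv]
                                                            if e2 == 0.0:
                                                                continue
                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                            acc += e1 * e2 * sgn * _Rtuv(
                                                                t + tt, u + uu, v + vv, 0, alpha, X, Y, Z, fb
                                                            )
                                    out[i, j, k, l] += pref * acc
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                for l in range(nd):
                    out[i, j, k, l] *= _CNRM[la, i] * _CNRM[lb, j] * _CNRM[lc, k] * _CNRM[ld, l]


@njit
def _eri_tensor(ls, nprim, ptr, exps, coefs, centers):
    """Full (nao,nao,nao,nao) two-electron tensor, 8-fold symmetry exploited."""
    nsh = ls.shape[0]
    nao_of = np.zeros(nsh + 1, dtype=np.int64)
    for i in range(nsh):
        nao_of[i + 1] = nao_of[i] + _NCOMP[ls[i]]
    nao = nao_of[nsh]
    eri = np.zeros((nao, nao, nao, nao))
    blk = np.zeros((6, 6, 6, 6))
    for si in range(nsh):
        for sj in range(si + 1):
            for sk in range(si + 1):
                lmax_l = sk if sk < si else sj
                for sl in range(lmax_l + 1):
                    if sk == si and sl > sj:
                        continue
                    _eri_quartet(
                        ls[si], ls[sj], ls[sk], ls[sl],
                        exps[ptr[si] : ptr[si] + nprim[si]],
                        exps[ptr[sj] : ptr[sj] + nprim[sj]],
                        exps[ptr[sk] : ptr[sk] + nprim[sk]],
                        exps[ptr[sl] : ptr[sl] + nprim[sl]],
                        coefs[ptr[si] : ptr[si] + nprim[si]],
                        coefs[ptr[sj] : ptr[sj] + nprim[sj]],
                        coefs[ptr[sk] : ptr[sk] + nprim[sk]],
                        coefs[ptr[sl] : ptr[sl] + nprim[sl]],
                        centers[si], centers[sj], centers[sk], centers[sl], blk,
                    )
                    for i in range(_NCOMP[ls[si]]):
                        mu = nao_of[si] + i
                        for j in range(_NCOMP[ls[sj]]):
                            nu = nao_of[sj] + j
                            for k in range(_NCOMP[ls[sk]]):
                                lam = nao_of[sk] + k
                                for l in range(_NCOMP[ls[sl]]):
                                    sig = nao_of[sl] + l
                                    v = blk[i, j, k, l]
                                    eri[mu, nu, lam, sig] = v
                                    eri[nu, mu, lam, sig] = v
                                    eri[mu, nu, sig, lam] = v
                                    eri[nu, mu, sig, lam] = v
                                    eri[lam, sig, mu, nu] = v
                                    eri[sig, lam, mu, nu] = v
                                    eri[lam, sig, nu, mu] = v
                                    eri[sig, lam, nu, mu] = v
    return eri


# ------------------------------------------------------------------ wrappers


def overlap(basis: BasisSet) -> np.ndarray:
    ls, npr, ptr, e, c, cen = basis.flat()
    z = np.zeros(0)
    return _one_electron(ls, npr, ptr, e, c, cen, z, np.zeros((0, 3)), 0)


def kinetic(basis: BasisSet) -> np.ndarray:
    ls, npr, ptr, e, c, cen = basis.flat()
    z = np.zeros(0)
    return _one_electron(ls, npr, ptr, e, c, cen, z, np.zeros((0, 3)), 1)


def nuclear_attraction(basis: BasisSet, charges: np.ndarray, coords: np.ndarray) -> np.ndarray:
    ls, npr, ptr, e, c, cen = basis.flat()
    return _one_electron(ls, npr, ptr, e, c, cen, np.asarray(charges, float), np.asarray(coords, float), 2)


def eri_tensor(basis: BasisSet) -> np.ndarray:
    ls, npr, ptr, e, c, cen = basis.flat()
    return _eri_tensor(ls, npr, ptr, e, c, cen)
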