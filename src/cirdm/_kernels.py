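"""Numba kernels: bitwise Slater-Condon elements and heavy accumulations.

Bitsets here are nonnegative ``int64`` (M <= 62); the pure-Python routines in
:mod:`cirdm.determinants` are the reference implementation for arbitrary M
and the property suite cross-checks the two.  Popcount uses a 16-bit table,
the lowest set bit comes from ``x & -x``.

Two-electron integrals are always physicists' ``<pr|qs>`` here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_POP16 = np.array([bin(i).count("1") for i in range(1 << 16)], dtype=np.int64)


@njit(cache=True)
def _popcnt(x):
    return (_POP16[x & 0xFFFF] + _POP16[(x >> 16) & 0xFFFF]
            + _POP16[(x >> 32) & 0xFFFF] + _POP16[(x >> 48) & 0xFFFF])


@njit(cache=True)
def _fill_occ(bits, out):
    """Write ascending occupied orbitals into ``out``; return the count."""
    n = 0
    while bits:
        low = bits & (-bits)
        out[n] = _popcnt(low - 1)
        n += 1
        bits ^= low
    return n


@njit(cache=True)
def _sign_between(bits, a, b):
    """Parity of set bits strictly between positions a and b."""
    if a > b:
        a, b = b, a
    mask = ((1 << b) - 1) ^ ((1 << (a + 1)) - 1)
    return -1 if _popcnt(bits & mask) & 1 else 1


@njit(cache=True)
def _diag_element(a, b, h, eri):
    """<D|H|D> for determinant bitsets (a, b)."""
    occa = np.empty(64, np.int64)
    occb = np.empty(64, np.int64)
    na = _fill_occ(a, occa)
    nb = _fill_occ(b, occb)
    val = 0.0
    for i in range(na):
        val += h[occa[i], occa[i]]
    for i in range(nb):
        val += h[occb[i], occb[i]]
    for i in range(na):
        p = occa[i]
        for j in range(i + 1, na):
            q = occa[j]
            val += eri[p, q, p, q] - eri[p, q, q, p]
    for i in range(nb):
        p = occb[i]
        for j in range(i + 1, nb):
            q = occb[j]
            val += eri[p, q, p, q] - eri[p, q, q, p]
    for i in range(na):
        p = occa[i]
        for j in range(nb):
            q = occb[j]
            val += eri[p, q, p, q]
    return val


@njit(cache=True)
def _lowbit_index(x):
    return _popcnt((x & (-x)) - 1)


@njit(cache=True)
def _single_value(i, j, same_bits, other_bits, h, eri):
    """Degree-1 value (unsigned): difference j -> i plus spectator sums."""
    occ = np.empty(64, np.int64)
    val = h[i, j]
    n = _fill_occ(same_bits, occ)
    for t in range(n):
        o = occ[t]
        val += eri[i, o, j, o] - eri[i, o, o, j]
    n = _fill_occ(other_bits, occ)
    for t in range(n):
        o = occ[t]
        val += eri[i, o, j, o]
    return val


@njit(cache=True)
def sc_element(a1, b1, a2, b2, h, eri):
    """Slater-Condon matrix element <D1|H|D2> via bit operations."""
    xa = a1 ^ a2
    xb = b1 ^ b2
    da = _popcnt(xa) >> 1
    db = _popcnt(xb) >> 1
    deg = da + db
    if deg > 2:
        return 0.0
    if deg == 0:
        return _diag_element(a1, b1, h, eri)
    if deg == 1:
        if da == 1:
            j = _lowbit_index(xa & a2)
            i = _lowbit_index(xa & a1)
            s = _sign_between(a2, j, i)
            return s * _single_value(i, j, a1 & a2, b2, h, eri)
        j = _lowbit_index(xb & b2)
        i = _lowbit_index(xb & b1)
        s = _sign_between(b2, j, i)
        return s * _single_value(i, j, b1 & b2, a2, h, eri)
    if da == 2:
        return _same_spin_double(a1, a2, xa, h, eri)
    if db == 2:
        return _same_spin_double(b1, b2, xb, h, eri)
    # mixed double: independent channel signs
    ja = _lowbit_index(xa & a2)
    ia = _lowbit_index(xa & a1)
    jb = _lowbit_index(xb & b2)
    ib = _lowbit_index(xb & b1)
    s = _sign_between(a2, ja, ia) * _sign_between(b2, jb, ib)
    return s * eri[ia, ib, ja, jb]


@njit(cache=True)
def _same_spin_double(s1, s2, diff, h, eri):
    hole = diff & s2
    part = diff & s1
    j1 = _lowbit_index(hole)
    j2 = _lowbit_index(hole ^ (hole & (-hole)))
    i1 = _lowbit_index(part)
    i2 = _lowbit_index(part ^ (part & (-part)))
    sgn = _sign_between(s2, j1, i1)
    mid = (s2 ^ (1 << j1)) | (1 << i1)
    sgn *= _sign_between(mid, j2, i2)
    return sgn * (eri[i1, i2, j1, j2] - eri[i1, i2, j2, j1])


@njit(cache=True)
def h_dense(alphas, betas, h, eri):
    """Dense symmetric Hamiltonian over an explicit determinant list."""
    n = len(alphas)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = sc_element(alphas[i], betas[i], alphas[j], betas[j], h, eri)
            out[i, j] = v
            out[j, i] = v
    return out


@njit(cache=True)
def h_rows(alphas, betas, rows, h, eri):
    """Selected rows of the determinant-list Hamiltonian."""
    out = np.zeros((len(rows), len(alphas)))
    for r in range(len(rows)):
        i = rows[r]
        for j in range(len(alphas)):
            out[r, j] = sc_element(alphas[i], betas[i], alphas[j], betas[j],
                                   h, eri)
    return out


@njit(cache=True)
def h_diag_dets(alphas, betas, h, eri):
    n = len(alphas)
    out = np.empty(n)
    for i in range(n):
        out[i] = _diag_element(alphas[i], betas[i], h, eri)
    return out


@njit(cache=True)
def _find_string(bits, vsorted, vperm):
    """Index of ``bits`` in the original string order via binary search."""
    lo, hi = 0, len(vsorted)
    while lo < hi:
        mid = (lo + hi) // 2
        if vsorted[mid] < bits:
            lo = mid + 1
        else:
            hi = mid
    return vperm[lo]


@njit(cache=True)
def channel_h_coo(strings, vsorted, vperm, M, h, eri):
    """Same-spin Hamiltonian of one string channel in COO form.

    Treats each string as a determinant with an empty opposite channel, so
    the entries are exactly the parts of H independent of the other spin
    (including the channel diagonal).
    """
    n = len(strings)
    occ = np.empty(64, np.int64)
    virt = np.empty(64, np.int64)
    if n == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
    no = _fill_occ(strings[0], occ)
    nv = M - no
    per = 1 + no * nv + (no * (no - 1) // 2) * (nv * (nv - 1) // 2)
    rows = np.empty(n * per, np.int64)
    cols = np.empty(n * per, np.int64)
    vals = np.empty(n * per)
    k = 0
    for I in range(n):
        s = strings[I]
        no = _fill_occ(s, occ)
        nv = 0
        for o in range(M):
            if not (s >> o) & 1:
                virt[nv] = o
                nv += 1
        rows[k] = I
        cols[k] = I
        vals[k] = _diag_element(s, 0, h, eri)
        k += 1
        for jj in range(no):
            q = occ[jj]
            for ii in range(nv):
                p = virt[ii]
                t = (s ^ (1 << q)) | (1 << p)
                J = _find_string(t, vsorted, vperm)
                sgn = _sign_between(s, q, p)
                rows[k] = J
                cols[k] = I
                vals[k] = sgn * _single_value(p, q, s & t, 0, h, eri)
                k += 1
        for j1 in range(no):
            for j2 in range(j1 + 1, no):
                q1, q2 = occ[j1], occ[j2]
                rem = s ^ (1 << q1) ^ (1 << q2)
                for i1 in range(nv):
                    for i2 in range(i1 + 1, nv):
                        p1, p2 = virt[i1], virt[i2]
                        t = rem | (1 << p1) | (1 << p2)
                        J = _find_string(t, vsorted, vperm)
                        sgn = _sign_between(s, q1, p1)
                        mid = (s ^ (1 << q1)) | (1 << p1)
                        sgn *= _sign_between(mid, q2, p2)
                        rows[k] = J
                        cols[k] = I
                        vals[k] = sgn * (eri[p1, p2, q1, q2]
                                         - eri[p1, p2, q2, q1])
                        k += 1
    return rows[:k], cols[:k], vals[:k]


@njit(cache=True)
def singles_tables(strings, vsorted, vperm, M):
    """Generalized single-excitation tables E_pq (p occupied, q the target).

    For each string I the entries are: the diagonal operators E_pp for every
    occupied p (target J = I, sign +1), then every proper single p -> q.
    Returns (targets, pq, signs) of shape (n, no*(nv+1)) with pq = p*M + q,
    meaning <J|a+_q a_p|I> = sign (for the diagonal, a+_p a_p).
    """
    n = len(strings)
    occ = np.empty(64, np.int64)
    virt = np.empty(64, np.int64)
    no = _fill_occ(strings[0], occ) if n else 0
    nv = M - no
    nt = no * (nv + 1)
    tJ = np.empty((n, nt), np.int64)
    tPQ = np.empty((n, nt), np.int64)
    tS = np.empty((n, nt))
    for I in range(n):
        s = strings[I]
        no = _fill_occ(s, occ)
        nv = 0
        for o in range(M):
            if not (s >> o) & 1:
                virt[nv] = o
                nv += 1
        k = 0
        for jj in range(no):
            p = occ[jj]
            tJ[I, k] = I
            tPQ[I, k] = p * M + p
            tS[I, k] = 1.0
            k += 1
        for jj in range(no):
            p = occ[jj]
            for ii in range(nv):
                q = virt[ii]
                t = (s ^ (1 << p)) | (1 << q)
                tJ[I, k] = _find_string(t, vsorted, vperm)
                tPQ[I, k] = p * M + q
                tS[I, k] = _sign_between(s, p, q)
                k += 1
    return tJ, tPQ, tS


@njit(cache=True)
def _deg1_update(G, p, q, w, occ_same, n_same, skip, occ_other, n_other):
    """Algorithm-2 pattern: one difference (particle p, hole q), spectators.

    ``occ_same`` holds the spectators sharing the spin of the difference
    (``skip`` marks the orbital p itself), ``occ_other`` the opposite spin.
    """
    for u in range(n_same):
        t = occ_same[u]
        if t == skip:
            continue
        G[p, t, t, q] += w
        G[t, p, q, t] += w
        G[p, t, q, t] -= w
        G[t, p, t, q] -= w
    for u in range(n_other):
        t = occ_other[u]
        G[p, t, t, q] += w
        G[t, p, q, t] += w


@njit(cache=True)
def _deg2_same_update(G, p1, p2, q1, q2, w):
    """Algorithm-1, same-spin case: all four pairings fire."""
    G[p1, p2, q2, q1] += w
    G[p2, p1, q1, q2] += w
    G[p1, p2, q1, q2] -= w
    G[p2, p1, q2, q1] -= w


@njit(cache=True)
def _deg0_update(G, occa, na, occb, nb, w):
    """Algorithm-3: every ordered pair of occupied spin orbitals."""
    for i in range(na):
        p = occa[i]
        for j in range(na):
            if i == j:
                continue
            q = occa[j]
            G[p, q, q, p] += w
            G[p, q, p, q] -= w
        for j in range(nb):
            q = occb[j]
            G[p, q, q, p] += w
            G[q, p, p, q] += w
    for i in range(nb):
        p = occb[i]
        for j in range(nb):
            if i == j:
                continue
            q = occb[j]
            G[p, q, q, p] += w
            G[p, q, p, q] -= w


@njit(cache=True)
def _channel_pass(C, tJ, tPQ, tS, occ_this, occ_oth, strings, vsorted, vperm,
                  M, G, do_deg0):
    """Degree-0/1/2 same-channel contributions for one spin channel.

    ``C`` is indexed [this, other].  Returns the determinant pairs visited.
    """
    n_this, n_oth = C.shape
    no = occ_this.shape[1]
    virt = np.empty(64, np.int64)
    visits = 0
    for I in range(n_this):
        s = strings[I]
        nv = 0
        for o in range(M):
            if not (s >> o) & 1:
                virt[nv] = o
                nv += 1
        if do_deg0:
            for K in range(n_oth):
                c = C[I, K]
                if c == 0.0:
                    continue
                visits += 1
                _deg0_update(G, occ_this[I], no, occ_oth[K],
                             occ_oth.shape[1], c * c)
        # proper singles: skip the no diagonal entries of the table
        for t in range(no, tJ.shape[1]):
            J = tJ[I, t]
            p = tPQ[I, t] // M
            q = tPQ[I, t] % M
            sgn = tS[I, t]
            for K in range(n_oth):
                cI = C[I, K]
                cJ = C[J, K]
                if cI == 0.0 or cJ == 0.0:
                    continue
                visits += 1
                # left det contains p (particle), right det contains q (hole)
                _deg1_update(G, p, q, sgn * cI * cJ, occ_this[I], no, p,
                             occ_oth[K], occ_oth.shape[1])
        # same-channel doubles
        for j1 in range(no):
            for j2 in range(j1 + 1, no):
                p1, p2 = occ_this[I, j1], occ_this[I, j2]
                rem = s ^ (1 << p1) ^ (1 << p2)
                for i1 in range(nv):
                    for i2 in range(i1 + 1, nv):
                        q1, q2 = virt[i1], virt[i2]
                        tgt = rem | (1 << q1) | (1 << q2)
                        J = _find_string(tgt, vsorted, vperm)
                        sgn = _sign_between(s, p1, q1)
                        mid = (s ^ (1 << p1)) | (1 << q1)
                        sgn = sgn * _sign_between(mid, p2, q2)
                        w = 0.0
                        for K in range(n_oth):
                            w += C[I, K] * C[J, K]
                        visits += n_oth
                        if w != 0.0:
                            _deg2_same_update(G, p1, p2, q1, q2, sgn * w)
    return visits


@njit(cache=True)
def _mixed_pass(C, tJa, tPQa, tSa, tJb, tPQb, tSb, noa, nob, M, G):
    """Mixed-spin double contributions (alpha single x beta single)."""
    na, nb = C.shape
    visits = 0
    for Ia in range(na):
        for ta in range(noa, tJa.shape[1]):
            Ja = tJa[Ia, ta]
            pa = tPQa[Ia, ta] // M
            qa = tPQa[Ia, ta] % M
            sa = tSa[Ia, ta]
            for Ib in range(nb):
                cI = C[Ia, Ib]
                if cI == 0.0:
                    continue
                for tb in range(nob, tJb.shape[1]):
                    cJ = C[Ja, tJb[Ib, tb]]
                    if cJ == 0.0:
                        continue
                    visits += 1
                    pb = tPQb[Ib, tb] // M
                    qb = tPQb[Ib, tb] % M
                    w = sa * tSb[Ib, tb] * cI * cJ
                    G[pa, pb, qb, qa] += w
                    G[pb, pa, qa, qb] += w
    return visits


def rdm2_fci_structured(C, strings_a, strings_b, sorted_a, sorted_b,
                        tables_a, tables_b, occ_a, occ_b, M):
    """Spin-free 2-RDM from a CI grid using the string excitation tables.

    ``sorted_x`` is a (values, permutation) pair for string lookup.  Serial
    deterministic accumulation; returns (Gamma, pair_visits).
    """
    G = np.zeros((M, M, M, M))
    CT = np.ascontiguousarray(C.T)
    visits = 0
    visits += _channel_pass(C, *tables_a, occ_a, occ_b, strings_a,
                            sorted_a[0], sorted_a[1], M, G, True)
    visits += _channel_pass(CT, *tables_b, occ_b, occ_a, strings_b,
                            sorted_b[0], sorted_b[1], M, G, False)
    noa = occ_a.shape[1]
    nob = occ_b.shape[1]
    visits += _mixed_pass(C, tables_a[0], tables_a[1], tables_a[2],
                          tables_b[0], tables_b[1], tables_b[2],
                          noa, nob, M, G)
    return G, visits
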