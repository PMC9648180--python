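"""Brute-force second-quantization oracle on a small Fock space.

Everything here is built from explicit creation/annihilation matrices over
all 4**M occupation states of 2M spin orbitals (M <= 4 keeps this instant).
The canonical spin-orbital ordering matches the package convention: all
alpha orbitals (ascending), then all beta — a determinant with string pair
(a, b) is the Fock basis state with bitmask a | (b << M).

This module is deliberately independent of the package internals: only the
bitmask convention is shared, so it can certify matrix elements, RDM
contributions, and spin operators.
"""

import numpy as np


def creation_matrix(spinorb: int, n_spinorb: int) -> np.ndarray:
    """Dense matrix of the creation operator for one spin orbital."""
    dim = 1 << n_spinorb
    mat = np.zeros((dim, dim))
    bit = 1 << spinorb
    for ket in range(dim):
        if ket & bit:
            continue
        sign = (-1) ** bin(ket & (bit - 1)).count("1")
        mat[ket | bit, ket] = sign
    return mat


class FockOracle:
    def __init__(self, M: int):
        self.M = M
        self.n_spinorb = 2 * M
        self.dim = 1 << self.n_spinorb
        self.cdag = [creation_matrix(o, self.n_spinorb)
                     for o in range(self.n_spinorb)]
        self.c = [m.T for m in self.cdag]

    def spinorb(self, p: int, spin: int) -> int:
        """Spin-orbital index: alpha block first, then beta."""
        return p + spin * self.M

    def det_index(self, alpha: int, beta: int) -> int:
        return alpha | (beta << self.M)

    def vector(self, wfn_items) -> np.ndarray:
        """Fock vector from an iterable of ((alpha, beta), coeff)."""
        v = np.zeros(self.dim)
        for (a, b), coef in wfn_items:
            v[self.det_index(a, b)] += coef
        return v

    def hamiltonian(self, h: np.ndarray, eri_phys: np.ndarray) -> np.ndarray:
        """H from <pr|qs> integrals (physicists' notation)."""
        M = self.M
        H = np.zeros((self.dim, self.dim))
        for p in range(M):
            for q in range(M):
                if h[p, q] == 0.0:
                    continue
                for s in (0, 1):
                    H += h[p, q] * (self.cdag[self.spinorb(p, s)]
                                    @ self.c[self.spinorb(q, s)])
        for p in range(M):
            for r in range(M):
                for q in range(M):
                    for s in range(M):
                        v = eri_phys[p, r, q, s]
                        if v == 0.0:
                            continue
                        for s1 in (0, 1):
                            for s2 in (0, 1):
                                H += 0.5 * v * (
                                    self.cdag[self.spinorb(p, s1)]
                                    @ self.cdag[self.spinorb(r, s2)]
                                    @ self.c[self.spinorb(s, s2)]
                                    @ self.c[self.spinorb(q, s1)])
        return H

    def rdm2_element(self, vec: np.ndarray, p, r, s, q) -> float:
        """Spin-free Gamma_prsq = sum_ss' <a+_ps a+_rs' a_ss' a_qs>."""
        val = 0.0
        for s1 in (0, 1):
            for s2 in (0, 1):
                op = (self.cdag[self.spinorb(p, s1)]
                      @ self.cdag[self.spinorb(r, s2)]
                      @ self.c[self.spinorb(s, s2)]
                      @ self.c[self.spinorb(q, s1)])
                val += vec @ op @ vec
        return val

    def rdm2(self, vec: np.ndarray) -> np.ndarray:
        M = self.M
        G = np.empty((M, M, M, M))
        for p in range(M):
            for r in range(M):
                for s in range(M):
                    for q in range(M):
                        G[p, r, s, q] = self.rdm2_element(vec, p, r, s, q)
        return G

    def rdm1(self, vec: np.ndarray) -> np.ndarray:
        M = self.M
        g = np.empty((M, M))
        for p in range(M):
            for q in range(M):
                val = 0.0
                for s1 in (0, 1):
                    op = (self.cdag[self.spinorb(p, s1)]
                          @ self.c[self.spinorb(q, s1)])
                    val += vec @ op @ vec
                g[p, q] = val
        return g

    def s2_matrix(self) -> np.ndarray:
        """S^2 = S- S+ + Sz (Sz + 1) as a dense Fock-space matrix."""
        M = self.M
        splus = np.zeros((self.dim, self.dim))
        sz = np.zeros((self.dim, self.dim))
        for p in range(M):
            splus += self.cdag[self.spinorb(p, 0)] @ self.c[self.spinorb(p, 1)]
            sz += 0.5 * (self.cdag[self.spinorb(p, 0)]
                         @ self.c[self.spinorb(p, 0)]
                         - self.cdag[self.spinorb(p, 1)]
                         @ self.c[self.spinorb(p, 1)])
        return splus.T @ splus + sz @ (sz + np.eye(self.dim))


def random_symmetric_integrals(M: int, rng) -> tuple:
    """(h, eri_phys) with full 8-fold real-orbital symmetry."""
    h = rng.standard_normal((M, M))
    h = (h + h.T) / 2
    eri = rng.standard_normal((M,) * 4)
    # symmetrize in chemists' convention, then permute to physicists'
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
        eri = (eri + eri.transpose(perm)) / 2
    eri_phys = eri.transpose(0, 2, 1, 3).copy()
    return h, eri_phys
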