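"""Orbital-string spaces: enumeration, addressing, and counting.

Strings of one spin channel are enumerated once, ordered by (irrep,
bitset value) so that each irrep occupies a contiguous block; excitation
tables and the same-spin Hamiltonian are built lazily from numba kernels.

Determinant-space sizes are always computed from per-irrep string
histograms — the alpha x beta pair grid is never enumerated.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .determinants import Determinant, string_irrep

__all__ = [
    "StringSpace",
    "enumerate_strings",
    "address_map",
    "count_determinants",
    "count_truncated",
]


class StringSpace:
    """All C(M, n) strings of one spin channel, with excitation tables."""

    def __init__(self, M: int, n: int, orbsym=None, irrep_filter=None):
        if not 0 <= n <= M:
            raise ValueError(f"need 0 <= n <= M, got n={n}, M={M}")
        self.M = M
        self.n = n
        self.orbsym = (np.zeros(M, dtype=np.int64) if orbsym is None
                       else np.asarray(orbsym, dtype=np.int64))
        values = _string_values(M, n)
        irreps = np.array([string_irrep(int(v), self.orbsym) for v in values],
                          dtype=np.int64)
        if irrep_filter is not None:
            keep = irreps == irrep_filter
            values, irreps = values[keep], irreps[keep]
        order = np.lexsort((values, irreps))
        self.strings = values[order]
        self.irreps = irreps[order]
        self.group_order = _pow2_order(self.orbsym)
        self.block_offsets = np.searchsorted(
            self.irreps, np.arange(self.group_order + 1))
        # value-sorted view for binary-search lookup
        vorder = np.argsort(self.strings, kind="stable")
        self.vsorted = self.strings[vorder]
        self.vperm = vorder.astype(np.int64)
        self._tables = None
        self._same_spin_h = None
        self._occ = None

    def __len__(self) -> int:
        return len(self.strings)

    def block(self, irrep: int) -> slice:
        """Contiguous index range of strings with the given irrep."""
        return slice(int(self.block_offsets[irrep]),
                     int(self.block_offsets[irrep + 1]))

    def address(self, bits: int) -> int:
        pos = int(np.searchsorted(self.vsorted, bits))
        if pos == len(self.vsorted) or self.vsorted[pos] != bits:
            raise KeyError(f"string {bits:b} not in space")
        return int(self.vperm[pos])

    @property
    def occ_lists(self) -> np.ndarray:
        """(n_strings, n) ascending occupied orbitals per string."""
        if self._occ is None:
            occ = np.empty((len(self.strings), self.n), dtype=np.int64)
            for i, s in enumerate(self.strings):
                s = int(s)
                k = 0
                while s:
                    low = s & -s
                    occ[i, k] = low.bit_length() - 1
                    k += 1
                    s ^= low
            self._occ = occ
        return self._occ

    @property
    def singles(self):
        """(targets, pq, signs) generalized single-excitation tables."""
        if self._tables is None:
            self._tables = _kernels.singles_tables(
                self.strings, self.vsorted, self.vperm, self.M)
        return self._tables

    def same_spin_h(self, ints) -> sp.csr_matrix:
        """Same-spin Hamiltonian (CSR), independent of the other channel."""
        if self._same_spin_h is None:
            if ints.notation != "physicists":
                raise ValueError("same_spin_h requires physicists' notation")
            rows, cols, vals = _kernels.channel_h_coo(
                self.strings, self.vsorted, self.vperm, self.M,
                ints.h, ints.eri)
            n = len(self.strings)
            self._same_spin_h = sp.coo_matrix(
                (vals, (rows, cols)), shape=(n, n)).tocsr()
        return self._same_spin_h

    def diag(self, ints) -> np.ndarray:
        return self.same_spin_h(ints).diagonal()


def enumerate_strings(M: int, n: int, orbsym=None,
                      irrep_filter=None) -> StringSpace:
    """Enumerate all C(M, n) strings (optionally one irrep) of a channel."""
    return StringSpace(M, n, orbsym=orbsym, irrep_filter=irrep_filter)


def _string_values(M: int, n: int) -> np.ndarray:
    vals = np.empty(comb(M, n), dtype=np.int64)
    for i, c in enumerate(combinations(range(M), n)):
        v = 0
        for o in c:
            v |= 1 << o
        vals[i] = v
    return vals


def _pow2_order(orbsym: np.ndarray) -> int:
    top = int(orbsym.max(initial=0))
    order = 1
    while order <= top:
        order *= 2
    return order


def address_map(alpha_loc: int, beta_loc: int, alpha_total: int) -> int:
    """1-based (alpha_loc, beta_loc) -> FCI vector location."""
    if not 1 <= alpha_loc <= alpha_total:
        raise ValueError(f"alpha_loc {alpha_loc} outside [1, {alpha_total}]")
    if beta_loc < 1:
        raise ValueError(f"beta_loc {beta_loc} < 1")
    return (beta_loc - 1) * alpha_total + alpha_loc


def _irrep_histogram(M: int, n: int, orbsym) -> dict:
    hist: dict = {}
    for c in combinations(range(M), n):
        g = 0
        for o in c:
            g ^= int(orbsym[o])
        hist[g] = hist.get(g, 0) + 1
    return hist


def count_determinants(M: int, n_alpha: int, n_beta: int, orbsym=None,
                       target_irrep=None) -> int:
    """Size of the (symmetry-restricted) determinant space.

    Uses per-irrep string histograms; the pair space itself is never built,
    so billion-determinant spaces count in well under a second.
    """
    if orbsym is None or target_irrep is None:
        return comb(M, n_alpha) * comb(M, n_beta)
    ha = _irrep_histogram(M, n_alpha, orbsym)
    hb = (_irrep_histogram(M, n_beta, orbsym) if n_beta != n_alpha else ha)
    return sum(v * hb.get(target_irrep ^ g, 0) for g, v in ha.items())


def _level_irrep_histogram(M: int, n: int, ref_bits: int, orbsym) -> dict:
    hist: dict = {}
    for c in combinations(range(M), n):
        g, bits = 0, 0
        for o in c:
            g ^= int(orbsym[o])
            bits |= 1 << o
        lev = n - (bits & ref_bits).bit_count()
        key = (lev, g)
        hist[key] = hist.get(key, 0) + 1
    return hist


def count_truncated(reference: Determinant, level: int, M: int, orbsym=None,
                    target_irrep=None) -> int:
    """Number of determinants within ``level`` substitutions of a reference.

    Computed from joint (excitation level, irrep) string histograms; Ms is
    fixed by the reference.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if orbsym is None:
        orbsym = np.zeros(M, dtype=np.int64)
    n_a = reference.alpha.bit_count()
    n_b = reference.beta.bit_count()
    ha = _level_irrep_histogram(M, n_a, reference.alpha, orbsym)
    hb = (_level_irrep_histogram(M, n_b, reference.beta, orbsym)
          if (n_b, reference.beta) != (n_a, reference.alpha) else ha)
    total = 0
    for (la, ga), va in ha.items():
        for (lb, gb), vb in hb.items():
            if la + lb > level:
                continue
            if target_irrep is not None and (ga ^ gb) != target_irrep:
                continue
            total += va * vb
    return total
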