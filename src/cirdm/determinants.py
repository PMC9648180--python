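"""Bitset orbital strings and Slater-Condon rules.

An orbital string is a plain Python integer whose bit ``i`` is set when
spatial orbital ``i`` is occupied for that spin channel (Python integers are
arbitrary precision, so any ``M`` is supported by one code path).  A
determinant is an (alpha, beta) pair of strings with the canonical operator
order *spin then orbital*: all alpha creation operators in ascending orbital
index, then all beta.  Every sign below is defined relative to that order.

The matrix-element rules use only bit operations: ``int.bit_count`` for
popcount and ``(s & -s).bit_length() - 1`` for the lowest set bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, NamedTuple

__all__ = [
    "Determinant",
    "ExcitationInfo",
    "occupied_orbitals",
    "string_from_orbitals",
    "excitation_degree",
    "excitation_info",
    "single_excitation_sign",
    "hamiltonian_element",
    "string_irrep",
    "enumerate_substitutions",
]


class Determinant(NamedTuple):
    alpha: int
    beta: int


@dataclass(frozen=True)
class ExcitationInfo:
    """Holes/particles per spin channel and the maximum-coincidence sign.

    Holes are occupied in the *second* determinant of the pair, particles in
    the first; both are ascending tuples.  ``sign`` is the parity factor from
    aligning the two operator strings.
    """

    degree: int
    holes_alpha: tuple
    particles_alpha: tuple
    holes_beta: tuple
    particles_beta: tuple
    sign: int


def string_from_orbitals(orbitals) -> int:
    s = 0
    for o in orbitals:
        s |= 1 << o
    return s


def occupied_orbitals(s: int) -> list:
    """Ascending orbital indices of the set bits (trailing-zeros loop)."""
    occ = []
    while s:
        low = s & -s
        occ.append(low.bit_length() - 1)
        s ^= low
    return occ


def string_irrep(s: int, orbsym) -> int:
    """XOR product of the irrep codes of the occupied orbitals."""
    g = 0
    while s:
        low = s & -s
        g ^= int(orbsym[low.bit_length() - 1])
        s ^= low
    return g


def excitation_degree(d1: Determinant, d2: Determinant) -> int:
    if (d1.alpha.bit_count() != d2.alpha.bit_count()
            or d1.beta.bit_count() != d2.beta.bit_count()):
        raise ValueError("determinants have mismatched electron counts")
    return ((d1.alpha ^ d2.alpha).bit_count()
            + (d1.beta ^ d2.beta).bit_count()) // 2


def single_excitation_sign(bits: int, hole: int, particle: int) -> int:
    """Parity of occupied orbitals strictly between hole and particle.

    ``bits`` is the string before the excitation (hole occupied, particle
    empty); beta-channel strings obey the same rule because the alpha block
    is crossed by one creation and one annihilation operator (even count).
    """
    lo, hi = (hole, particle) if hole < particle else (particle, hole)
    mask = ((1 << hi) - 1) ^ ((1 << (lo + 1)) - 1)
    return -1 if (bits & mask).bit_count() & 1 else 1


def _channel_diff(s1: int, s2: int):
    """(holes, particles, sign) for one spin channel, excitation d2 -> d1."""
    diff = s1 ^ s2
    holes = occupied_orbitals(diff & s2)
    particles = occupied_orbitals(diff & s1)
    sign = 1
    cur = s2
    for h, p in zip(holes, particles):
        sign *= single_excitation_sign(cur, h, p)
        cur = (cur ^ (1 << h)) | (1 << p)
    return tuple(holes), tuple(particles), sign


def excitation_info(d1: Determinant, d2: Determinant) -> ExcitationInfo:
    """Slater-Condon bookkeeping for a pair at excitation degree <= 2."""
    degree = excitation_degree(d1, d2)
    if degree > 2:
        raise ValueError(f"excitation degree {degree} > 2")
    ha, pa, sa = _channel_diff(d1.alpha, d2.alpha)
    hb, pb, sb = _channel_diff(d1.beta, d2.beta)
    return ExcitationInfo(degree=degree, holes_alpha=ha, particles_alpha=pa,
                          holes_beta=hb, particles_beta=pb, sign=sa * sb)


def hamiltonian_element(d1: Determinant, d2: Determinant, ints) -> float:
    """<d1|H|d2> with physicists'-notation integrals ``<pr|qs>``.

    Degree 0: occupied one-electron sum plus pairwise Coulomb minus
    same-spin exchange.  Degree 1: signed one-electron term plus spectator
    sum.  Degree 2: signed (anti)symmetrized two-electron integral.
    Degree > 2: exactly zero.
    """
    if ints.notation != "physicists":
        raise ValueError("hamiltonian_element requires physicists' notation")
    degree = excitation_degree(d1, d2)
    if degree > 2:
        return 0.0
    h, eri = ints.h, ints.eri

    if degree == 0:
        occ_a = occupied_orbitals(d1.alpha)
        occ_b = occupied_orbitals(d1.beta)
        val = sum(h[p, p] for p in occ_a) + sum(h[p, p] for p in occ_b)
        for i, p in enumerate(occ_a):
            for q in occ_a[i + 1:]:
                val += eri[p, q, p, q] - eri[p, q, q, p]
        for i, p in enumerate(occ_b):
            for q in occ_b[i + 1:]:
                val += eri[p, q, p, q] - eri[p, q, q, p]
        for p in occ_a:
            for q in occ_b:
                val += eri[p, q, p, q]
        return float(val)

    info = excitation_info(d1, d2)
    if degree == 1:
        if info.holes_alpha:
            (j,), (i,) = info.holes_alpha, info.particles_alpha
            same = occupied_orbitals(d2.alpha & d1.alpha)
            other = occupied_orbitals(d2.beta)
        else:
            (j,), (i,) = info.holes_beta, info.particles_beta
            same = occupied_orbitals(d2.beta & d1.beta)
            other = occupied_orbitals(d2.alpha)
        val = h[i, j]
        for t in same:
            val += eri[i, t, j, t] - eri[i, t, t, j]
        for t in other:
            val += eri[i, t, j, t]
        return float(info.sign * val)

    # degree == 2
    if len(info.holes_alpha) == 2:
        (j1, j2), (i1, i2) = info.holes_alpha, info.particles_alpha
        return float(info.sign * (eri[i1, i2, j1, j2] - eri[i1, i2, j2, j1]))
    if len(info.holes_beta) == 2:
        (j1, j2), (i1, i2) = info.holes_beta, info.particles_beta
        return float(info.sign * (eri[i1, i2, j1, j2] - eri[i1, i2, j2, j1]))
    (ja,), (ia,) = info.holes_alpha, info.particles_alpha
    (jb,), (ib,) = info.holes_beta, info.particles_beta
    return float(info.sign * eri[ia, ib, ja, jb])


def _single_strings(bits: int, M: int):
    occ = occupied_orbitals(bits)
    for j in occ:
        for i in range(M):
            if not (bits >> i) & 1:
                yield (bits ^ (1 << j)) | (1 << i)


def _double_strings(bits: int, M: int):
    occ = occupied_orbitals(bits)
    virt = [i for i in range(M) if not (bits >> i) & 1]
    for j1, j2 in combinations(occ, 2):
        removed = bits ^ (1 << j1) ^ (1 << j2)
        for i1, i2 in combinations(virt, 2):
            yield removed | (1 << i1) | (1 << i2)


def enumerate_substitutions(d: Determinant, max_level: int, M: int,
                            orbsym=None, target_irrep=None
                            ) -> Iterator[Determinant]:
    """Yield each distinct single (and double) substitution exactly once.

    Ms is conserved by construction; if ``target_irrep`` is given together
    with ``orbsym``, only determinants of that overall irrep are yielded.
    """
    if max_level not in (1, 2):
        raise ValueError("max_level must be 1 or 2")

    def allowed(det):
        if target_irrep is None:
            return True
        g = string_irrep(det.alpha, orbsym) ^ string_irrep(det.beta, orbsym)
        return g == target_irrep

    for a in _single_strings(d.alpha, M):
        cand = Determinant(a, d.beta)
        if allowed(cand):
            yield cand
    for b in _single_strings(d.beta, M):
        cand = Determinant(d.alpha, b)
        if allowed(cand):
            yield cand
    if max_level == 2:
        for a in _double_strings(d.alpha, M):
            cand = Determinant(a, d.beta)
            if allowed(cand):
                yield cand
        for b in _double_strings(d.beta, M):
            cand = Determinant(d.alpha, b)
            if allowed(cand):
                yield cand
        for a in _single_strings(d.alpha, M):
            for b in _single_strings(d.beta, M):
                cand = Determinant(a, b)
                if allowed(cand):
                    yield cand
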