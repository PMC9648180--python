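"""Spin-free reduced density matrices from determinant expansions.

The two-electron matrix follows the convention WITHOUT the absorbed factor
of one half: ``Gamma[p, r, s, q]`` is the spin-summed expectation of
``a+_{p sigma} a+_{r sigma'} a_{s sigma'} a_{q sigma}``, so the electronic
energy is ``sum h_pq gamma_pq + 1/2 sum <pr|qs> Gamma_prsq``.

Four construction strategies are provided and must agree elementwise:

1. naive all-pairs with orbital-then-spin operator ordering (generic
   maximum-coincidence signs on spin-orbital lists),
2. naive all-pairs with bitwise spin-then-orbital machinery,
3. like 2 but visiting only i <= j and restoring hermiticity at the end,
4. the FCI-structured builder that walks precomputed string excitation
   tables and visits only linked pairs (O(N_SD M^2)),

plus the search-based builder for general selected-CI expansions, which
generates each determinant's substitutions and binary-searches them in the
expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .determinants import (Determinant, ExcitationInfo, excitation_degree,
                           excitation_info, occupied_orbitals)
from .fci import CIVector
from .integrals import PHYSICISTS, SpinFreeIntegrals
from .wavefunction import WavefunctionSD

__all__ = [
    "RDM1", "RDM2",
    "rdm2_naive", "rdm2_from_fci", "rdm2_from_sd_list",
    "rdm2_update_two_diff", "rdm2_update_one_diff", "rdm2_update_no_diff",
    "rdm1_direct", "rdm1_from_rdm2", "energy_from_rdms",
    "write_rdm2_text", "read_rdm2_text",
]

CONVENTION = "no-half"


@dataclass
class RDM2:
    """Spin-free 2-RDM Gamma_prsq (dimensionless occupancies)."""

    gamma: np.ndarray
    M: int
    n_elec: int
    convention: str = CONVENTION
    pair_visits: int = field(default=0, compare=False)

    def trace(self) -> float:
        return float(np.einsum("prrp->", self.gamma))

    def validate(self, tol: float = 1e-9) -> None:
        g = self.gamma
        expected = self.n_elec * (self.n_elec - 1)
        if abs(self.trace() - expected) > tol:
            raise ValueError(f"trace {self.trace()} != N(N-1) = {expected}")
        if not np.allclose(g, g.transpose(1, 0, 3, 2), atol=1e-12):
            raise ValueError("Gamma_prsq != Gamma_rpqs")
        diag = np.einsum("prrp->pr", g)
        if diag.min() < -1e-12:
            raise ValueError("negative pair occupancy on the diagonal")


@dataclass
class RDM1:
    """Spin-free 1-RDM gamma_pq."""

    gamma: np.ndarray
    M: int
    n_elec: int

    def validate(self, tol: float = 1e-9) -> None:
        if not np.allclose(self.gamma, self.gamma.T, atol=1e-12):
            raise ValueError("1-RDM not symmetric")
        if abs(np.trace(self.gamma) - self.n_elec) > tol:
            raise ValueError("1-RDM trace != N_e")
        w = np.linalg.eigvalsh(self.gamma)
        if w.min() < -1e-9 or w.max() > 2 + 1e-9:
            raise ValueError("1-RDM occupation outside [0, 2]")


# ---------------------------------------------------------------------------
# elementary updates (Algorithms 1-3 reconstructed; certified by the
# second-quantization oracle in the test suite)
# ---------------------------------------------------------------------------

def _spin_diffs(info: ExcitationInfo):
    """Particles/holes as (orbital, spin) lists; spin 0=alpha, 1=beta."""
    parts = ([(p, 0) for p in info.particles_alpha]
             + [(p, 1) for p in info.particles_beta])
    holes = ([(q, 0) for q in info.holes_alpha]
             + [(q, 1) for q in info.holes_beta])
    return parts, holes


def rdm2_update_two_diff(G: np.ndarray, c_i: float, c_j: float,
                         info: ExcitationInfo) -> None:
    """Degree-2 contribution of the ordered pair (i left, j right).

    Four pairings of the two creation with the two annihilation differences;
    each fires only when the spins match, with alternating sign.
    """
    if info.degree != 2:
        raise ValueError("rdm2_update_two_diff needs a degree-2 pair")
    (p1, s1), (p2, s2) = _spin_diffs(info)[0]
    (q1, t1), (q2, t2) = _spin_diffs(info)[1]
    w = info.sign * c_i * c_j
    if s1 == t1 and s2 == t2:
        G[p1, p2, q2, q1] += w
        G[p2, p1, q1, q2] += w
    if s1 == t2 and s2 == t1:
        G[p1, p2, q1, q2] -= w
        G[p2, p1, q2, q1] -= w


def rdm2_update_one_diff(G: np.ndarray, c_i: float, c_j: float,
                         info: ExcitationInfo, spectators) -> None:
    """Degree-1 contribution; ``spectators`` are common (orbital, spin)."""
    if info.degree != 1:
        raise ValueError("rdm2_update_one_diff needs a degree-1 pair")
    [(p, s)], [(q, _)] = _spin_diffs(info)
    w = info.sign * c_i * c_j
    for (t, ts) in spectators:
        G[p, t, t, q] += w
        G[t, p, q, t] += w
        if ts == s:
            G[p, t, q, t] -= w
            G[t, p, t, q] -= w


def rdm2_update_no_diff(G: np.ndarray, c_sq: float, det: Determinant) -> None:
    """Diagonal contribution: all ordered pairs of occupied spin orbitals."""
    occ = ([(p, 0) for p in occupied_orbitals(det.alpha)]
           + [(p, 1) for p in occupied_orbitals(det.beta)])
    for i, (p, s) in enumerate(occ):
        for j, (q, t) in enumerate(occ):
            if i == j:
                continue
            G[p, q, q, p] += c_sq
            if s == t:
                G[p, q, p, q] -= c_sq


def _spectators(det: Determinant, info: ExcitationInfo):
    """Occupied spin orbitals of the left determinant minus its particle."""
    if info.particles_alpha:
        p = info.particles_alpha[0]
        return ([(t, 0) for t in occupied_orbitals(det.alpha) if t != p]
                + [(t, 1) for t in occupied_orbitals(det.beta)])
    p = info.particles_beta[0]
    return ([(t, 0) for t in occupied_orbitals(det.alpha)]
            + [(t, 1) for t in occupied_orbitals(det.beta) if t != p])


# ---------------------------------------------------------------------------
# strategy 1: orbital-then-spin generic algorithm
# ---------------------------------------------------------------------------

def _orbital_spin_list(det: Determinant):
    """Spin orbitals in orbital-major order, encoded 2*p + spin."""
    return sorted([2 * p for p in occupied_orbitals(det.alpha)]
                  + [2 * p + 1 for p in occupied_orbitals(det.beta)])


def _interleave_phase(det: Determinant) -> int:
    """Relative phase between spin-major and orbital-major orderings."""
    occ_a = occupied_orbitals(det.alpha)
    occ_b = occupied_orbitals(det.beta)
    inv = sum(1 for p in occ_a for q in occ_b if q < p)
    return -1 if inv & 1 else 1


def _list_pair_info(left, right) -> ExcitationInfo:
    """Maximum-coincidence analysis on orbital-major spin-orbital lists."""
    sl, sr = set(left), set(right)
    parts = sorted(sl - sr)   # in left only
    holes = sorted(sr - sl)   # in right only
    aligned = list(right)
    # spin is conserved: align holes with particles within each spin channel
    for sigma in (0, 1):
        hs = [q for q in holes if q % 2 == sigma]
        ps = [p for p in parts if p % 2 == sigma]
        for h, p in zip(hs, ps):
            aligned[aligned.index(h)] = p
    inv = sum(1 for i in range(len(aligned)) for j in range(i + 1, len(aligned))
              if aligned[i] > aligned[j])
    sign = -1 if inv & 1 else 1
    ha = tuple(q // 2 for q in holes if q % 2 == 0)
    hb = tuple(q // 2 for q in holes if q % 2 == 1)
    pa = tuple(p // 2 for p in parts if p % 2 == 0)
    pb = tuple(p // 2 for p in parts if p % 2 == 1)
    return ExcitationInfo(degree=len(parts), holes_alpha=ha,
                          particles_alpha=pa, holes_beta=hb,
                          particles_beta=pb, sign=sign)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def rdm2_naive(wfn: WavefunctionSD, strategy: int = 2) -> RDM2:
    """2-RDM by explicit loops over determinant pairs.

    Strategy 1 re-derives every sign from orbital-then-spin operator lists,
    2 uses the bitwise spin-then-orbital machinery over all ordered pairs,
    and 3 restricts to i <= j and symmetrizes.  All three agree elementwise.
    """
    if strategy not in (1, 2, 3):
        raise ValueError("strategy must be 1, 2, or 3")
    _check_normalized(wfn)
    M = len(wfn.coeffs) and wfn.M or wfn.M
    dets = [Determinant(int(a), int(b))
            for a, b in zip(wfn.alphas, wfn.betas)]
    c = wfn.coeffs
    G = np.zeros((wfn.M,) * 4)
    visits = 0

    if strategy == 1:
        lists = [_orbital_spin_list(d) for d in dets]
        phase = np.array([_interleave_phase(d) for d in dets], dtype=float)
        cc = c * phase
        for i, di in enumerate(dets):
            rdm2_update_no_diff(G, cc[i] * cc[i], di)
            for j, dj in enumerate(dets):
                if i == j:
                    continue
                info = _list_pair_info(lists[i], lists[j])
                visits += 1
                if info.degree == 1:
                    rdm2_update_one_diff(G, cc[i], cc[j], info,
                                         _spectators(di, info))
                elif info.degree == 2:
                    rdm2_update_two_diff(G, cc[i], cc[j], info)
        return RDM2(G, wfn.M, wfn.n_elec, pair_visits=visits)

    for i, di in enumerate(dets):
        rdm2_update_no_diff(G, c[i] * c[i], di)
        j_range = range(i + 1, len(dets)) if strategy == 3 else range(len(dets))
        for j in j_range:
            if j == i:
                continue
            dj = dets[j]
            deg = excitation_degree(di, dj)
            visits += 1
            if deg > 2 or deg == 0:
                continue
            info = excitation_info(di, dj)
            if deg == 1:
                rdm2_update_one_diff(G, c[i], c[j], info,
                                     _spectators(di, info))
            else:
                rdm2_update_two_diff(G, c[i], c[j], info)
    if strategy == 3:
        # restore hermiticity: Gamma_prsq += Gamma_qspr of the upper pairs
        diag = np.zeros_like(G)
        for i, di in enumerate(dets):
            rdm2_update_no_diff(diag, c[i] * c[i], di)
        off = G - diag
        G = diag + off + off.transpose(3, 2, 1, 0)
    return RDM2(G, wfn.M, wfn.n_elec, pair_visits=visits)


def rdm2_from_sd_list(wfn: WavefunctionSD) -> RDM2:
    """Search-based 2-RDM for a general (selected-CI) SD expansion.

    For each determinant, its single and double substitutions are generated
    and binary-searched in the sorted expansion; only hits contribute.
    """
    _check_normalized(wfn)
    keys = wfn.keys()
    if np.any(np.diff(keys) <= 0):
        raise ValueError("wavefunction must be sorted by canonical key")
    M = wfn.M
    G = np.zeros((M,) * 4)
    visits = 0
    dets = [Determinant(int(a), int(b))
            for a, b in zip(wfn.alphas, wfn.betas)]
    from .determinants import enumerate_substitutions
    for i, di in enumerate(dets):
        ci = float(wfn.coeffs[i])
        rdm2_update_no_diff(G, ci * ci, di)
        for dj in enumerate_substitutions(di, 2, M):
            j = wfn.index_of(dj)
            if j < 0:
                continue
            visits += 1
            cj = float(wfn.coeffs[j])
            info = excitation_info(di, dj)
            if info.degree == 1:
                rdm2_update_one_diff(G, ci, cj, info, _spectators(di, info))
            else:
                rdm2_update_two_diff(G, ci, cj, info)
    return RDM2(G, M, wfn.n_elec, pair_visits=visits)


def rdm2_from_fci(state: CIVector, ints=None) -> RDM2:
    """2-RDM from a string-FCI state using the precomputed tables.

    Visits only determinant pairs linked by singles/doubles through the
    per-channel excitation tables; serial deterministic accumulation.
    The ``pair_visits`` counter on the result exposes the O(N_SD M^2) walk.
    """
    sa, sb = state.space_a, state.space_b
    M = sa.M
    G, visits = _kernels.rdm2_fci_structured(
        np.ascontiguousarray(state.C), sa.strings, sb.strings,
        (sa.vsorted, sa.vperm), (sb.vsorted, sb.vperm),
        sa.singles, sb.singles, sa.occ_lists, sb.occ_lists, M)
    n_elec = sa.n + sb.n
    return RDM2(G, M, n_elec, pair_visits=int(visits))


def rdm1_direct(wfn: WavefunctionSD) -> RDM1:
    """1-RDM by direct evaluation over degree <= 1 determinant pairs."""
    _check_normalized(wfn)
    M = wfn.M
    g = np.zeros((M, M))
    dets = [Determinant(int(a), int(b))
            for a, b in zip(wfn.alphas, wfn.betas)]
    c = wfn.coeffs
    for i, di in enumerate(dets):
        for p in occupied_orbitals(di.alpha):
            g[p, p] += c[i] * c[i]
        for p in occupied_orbitals(di.beta):
            g[p, p] += c[i] * c[i]
        for j, dj in enumerate(dets):
            if i == j or excitation_degree(di, dj) != 1:
                continue
            info = excitation_info(di, dj)
            [(p, _)], [(q, _)] = _spin_diffs(info)
            g[p, q] += info.sign * c[i] * c[j]
    return RDM1(g, M, wfn.n_elec)


def rdm1_from_rdm2(rdm2: RDM2, n_elec: int = None) -> RDM1:
    """Contract the 2-RDM down to the 1-RDM: gamma = sum_r Gamma_prrq/(N-1)."""
    if n_elec is None:
        n_elec = rdm2.n_elec
    if n_elec < 2:
        raise ValueError("contraction requires at least two electrons")
    g = np.einsum("prrq->pq", rdm2.gamma) / (n_elec - 1)
    return RDM1(g, rdm2.M, n_elec)


def energy_from_rdms(ints: SpinFreeIntegrals, rdm1: RDM1,
                     rdm2: RDM2) -> float:
    """E = sum h_pq gamma_pq + 1/2 sum <pr|qs> Gamma_prsq + E_core."""
    if ints.notation != PHYSICISTS:
        raise ValueError("energy_from_rdms requires physicists' notation")
    if rdm2.convention != CONVENTION:
        raise ValueError(f"2-RDM convention {rdm2.convention!r} not supported")
    e1 = float(np.einsum("pq,pq->", ints.h, rdm1.gamma))
    e2 = 0.5 * float(np.einsum("prqs,prsq->", ints.eri, rdm2.gamma))
    return e1 + e2 + ints.e_core


def _check_normalized(wfn: WavefunctionSD, tol: float = 1e-8) -> None:
    if abs(wfn.norm - 1.0) > tol:
        raise ValueError(f"wavefunction norm {wfn.norm} is not 1")


# ---------------------------------------------------------------------------
# plain-text sparse interchange
# ---------------------------------------------------------------------------

def write_rdm2_text(rdm2: RDM2, path, tol: float = 1e-14) -> None:
    """Self-describing sparse dump: header metadata plus 'p r s q value'."""
    with open(path, "w") as f:
        f.write(f"# 2-RDM M={rdm2.M} N_e={rdm2.n_elec} "
                f"convention={rdm2.convention}\n")
        it = np.nditer(rdm2.gamma, flags=["multi_index"])
        for v in it:
            if abs(v) > tol:
                p, r, s, q = it.multi_index
                f.write(f"{p} {r} {s} {q} {float(v):.16e}\n")


def read_rdm2_text(path) -> RDM2:
    with open(path) as f:
        header = f.readline().split()
        meta = dict(kv.split("=") for kv in header if "=" in kv)
        M = int(meta["M"])
        G = np.zeros((M,) * 4)
        for line in f:
            p, r, s, q, v = line.split()
            G[int(p), int(r), int(s), int(q)] = float(v)
    return RDM2(G, M, int(meta["N_e"]), convention=meta["convention"])
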