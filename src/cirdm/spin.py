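"""Spin operators on determinant expansions and Lowdin spin projection.

Wavefunctions here are ``{(alpha, beta): coeff}`` dictionaries (or
:class:`WavefunctionSD`); S^2 is applied exactly through ladder operators,
S^2 = S- S+ + Sz (Sz + 1), with signs from the canonical
spin-then-orbital operator order.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isclose

from .determinants import Determinant
from .wavefunction import WavefunctionSD

__all__ = [
    "SpinProjectionTask", "apply_s2", "s2_expectation", "spin_project",
    "spin_error", "expand_csfs",
]

MERGE_TOL = 1e-12


def _as_dict(wfn) -> dict:
    if isinstance(wfn, WavefunctionSD):
        return wfn.to_dict()
    return dict(wfn)


def _bits_below(bits: int, p: int) -> int:
    return (bits & ((1 << p) - 1)).bit_count()


def _apply_splus(data: dict) -> dict:
    """S+ = sum_p a+_{p,alpha} a_{p,beta}: flip one beta to alpha."""
    out: dict = {}
    for (a, b), c in data.items():
        na = a.bit_count()
        flippable = b & ~a
        while flippable:
            low = flippable & -flippable
            p = low.bit_length() - 1
            flippable ^= low
            # annihilate beta p (crosses the alpha block and lower betas),
            # then create alpha p
            sign = (-1) ** (na + _bits_below(b, p)) * (-1) ** _bits_below(a, p)
            key = (a | low, b ^ low)
            out[key] = out.get(key, 0.0) + sign * c
    return {k: v for k, v in out.items() if abs(v) > 0.0}


def _apply_sminus(data: dict) -> dict:
    """S- = sum_p a+_{p,beta} a_{p,alpha}."""
    out: dict = {}
    for (a, b), c in data.items():
        flippable = a & ~b
        while flippable:
            low = flippable & -flippable
            p = low.bit_length() - 1
            flippable ^= low
            na_after = a.bit_count() - 1
            sign = (-1) ** _bits_below(a, p) \
                * (-1) ** (na_after + _bits_below(b, p))
            key = (a ^ low, b | low)
            out[key] = out.get(key, 0.0) + sign * c
    return {k: v for k, v in out.items() if abs(v) > 0.0}


def _check_fixed_ms(data: dict) -> int:
    ms2 = None
    for (a, b) in data:
        m = a.bit_count() - b.bit_count()
        if ms2 is None:
            ms2 = m
        elif m != ms2:
            raise ValueError("expansion mixes different Ms values")
    return 0 if ms2 is None else ms2


def apply_s2(wfn, M: int = None):
    """S^2 |Psi> as a determinant expansion (Ms is preserved)."""
    data = _as_dict(wfn)
    ms2 = _check_fixed_ms(data)
    ms = ms2 / 2.0
    out = _apply_sminus(_apply_splus(data))
    for k, c in data.items():
        out[k] = out.get(k, 0.0) + ms * (ms + 1.0) * c
    out = {k: v for k, v in out.items() if abs(v) > MERGE_TOL}
    if isinstance(wfn, WavefunctionSD):
        return WavefunctionSD.from_dict(wfn.M, out)
    return out


def _overlap(d1: dict, d2: dict) -> float:
    if len(d2) < len(d1):
        d1, d2 = d2, d1
    return sum(c * d2.get(k, 0.0) for k, c in d1.items())


def s2_expectation(wfn) -> float:
    """<Psi|S^2|Psi> / <Psi|Psi> via ladder-operator application."""
    data = _as_dict(wfn)
    nrm = _overlap(data, data)
    if nrm <= 0.0:
        raise ValueError("zero-norm wavefunction")
    return _overlap(data, apply_s2(data)) / nrm


def spin_error(wfn, S: float) -> float:
    """|<S^2> - S(S+1)|, the spin-contamination measure."""
    return abs(s2_expectation(wfn) - S * (S + 1.0))


@dataclass(frozen=True)
class SpinProjectionTask:
    """One CSF: a seed determinant's occupation plus a target spin k."""

    M: int
    doubly: tuple
    unpaired: tuple
    k: float
    ms2: int

    def __post_init__(self):
        if set(self.doubly) & set(self.unpaired):
            raise ValueError("doubly and unpaired orbital lists overlap")
        n_up = len(self.unpaired)
        if abs(self.ms2) > n_up or (n_up - self.ms2) % 2:
            raise ValueError("ms2 incompatible with unpaired electron count")
        if not (abs(self.ms2) / 2.0 <= self.k + 1e-12 <= n_up / 2.0 + 1e-12):
            raise ValueError("k outside [|Ms|, n_unpaired/2]")

    def seed_determinant(self) -> Determinant:
        """Alpha on the first (n_up + ms2)/2 unpaired orbitals."""
        closed = 0
        for p in self.doubly:
            closed |= 1 << p
        n_alpha_up = (len(self.unpaired) + self.ms2) // 2
        a, b = closed, closed
        for i, p in enumerate(sorted(self.unpaired)):
            if i < n_alpha_up:
                a |= 1 << p
            else:
                b |= 1 << p
        return Determinant(a, b)

    def spin_values(self):
        """Attainable S values for this occupation (same parity as n/2)."""
        n_up = len(self.unpaired)
        smax = n_up / 2.0
        smin = abs(self.ms2) / 2.0
        vals = []
        s = smax
        while s >= smin - 1e-12:
            vals.append(s)
            s -= 1.0
        return vals


def spin_project(task: SpinProjectionTask) -> WavefunctionSD:
    """Lowdin projection of the seed determinant onto spin k.

    Applies prod_{r != k} (S^2 - r(r+1)) / (k(k+1) - r(r+1)) with exact
    denominators, merging duplicate determinants after every factor.
    Returns a normalized expansion with <S^2> = k(k+1), or an empty
    wavefunction when the k-component is absent from the seed.
    """
    seed = task.seed_determinant()
    data = {(seed.alpha, seed.beta): 1.0}
    kk = task.k * (task.k + 1.0)
    for r in sorted(task.spin_values()):
        if isclose(r, task.k):
            continue
        rr = r * (r + 1.0)
        s2 = apply_s2(data)
        new = {}
        for key in set(data) | set(s2):
            v = (s2.get(key, 0.0) - rr * data.get(key, 0.0)) / (kk - rr)
            if abs(v) > MERGE_TOL:
                new[key] = v
        data = new
    wfn = WavefunctionSD.from_dict(task.M, data)
    if wfn.norm < 1e-10:
        return WavefunctionSD.from_dict(task.M, {})
    return wfn.normalized()


def expand_csfs(tasks, coeffs=None) -> WavefunctionSD:
    """Project several CSFs and merge them with a global duplicate removal."""
    if coeffs is None:
        coeffs = [1.0] * len(tasks)
    merged: dict = {}
    M = tasks[0].M
    for task, w in zip(tasks, coeffs):
        part = spin_project(task)
        for det, c in part:
            key = (det.alpha, det.beta)
            merged[key] = merged.get(key, 0.0) + w * c
    merged = {k: v for k, v in merged.items() if abs(v) > MERGE_TOL}
    wfn = WavefunctionSD.from_dict(M, merged)
    return wfn.normalized() if wfn.norm > 1e-10 else wfn
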