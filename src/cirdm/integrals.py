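"""Molecular-orbital integrals: FCIDUMP I/O, notation conversion, frozen core.

The in-memory container :class:`SpinFreeIntegrals` carries the one-electron
matrix ``h``, the 4-index two-electron table ``eri`` (with an explicit
notation flag, chemists' ``(pq|rs)`` or physicists' ``<pr|qs>``), the scalar
core energy, and per-orbital irrep codes of an abelian point group in an
XOR-multiplicative encoding.

On disk the canonical interchange format is FCIDUMP (``&FCI`` namelist,
1-based indices, one symmetry-unique record per line).  ORBSYM is stored in
the MOLPRO convention; for D2h and its subgroups ``code - 1`` multiplies by
bitwise XOR, which is the encoding used internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SpinFreeIntegrals",
    "FcidumpFormatError",
    "read_fcidump",
    "write_fcidump",
    "convert_notation",
    "fold_frozen_core",
    "restore_eri_symmetry",
    "MOLPRO_IRREP_NAMES",
]

CHEMISTS = "chemists"
PHYSICISTS = "physicists"

# MOLPRO 1-based irrep ordering per point group; (code - 1) is
# XOR-multiplicative for every D2h subgroup.
MOLPRO_IRREP_NAMES = {
    "D2h": ["Ag", "B3u", "B2u", "B1g", "B1u", "B2g", "B3g", "Au"],
    "C2v": ["A1", "B1", "B2", "A2"],
    "C2h": ["Ag", "Au", "Bu", "Bg"],
    "D2": ["A", "B3", "B2", "B1"],
    "C2": ["A", "B"],
    "Cs": ["A'", "A\""],
    "Ci": ["Ag", "Au"],
    "C1": ["A"],
}


class FcidumpFormatError(ValueError):
    """Raised when an FCIDUMP file violates the expected dialect."""


@dataclass
class SpinFreeIntegrals:
    """Spin-free molecular integrals over ``M`` real spatial orbitals."""

    M: int
    n_elec: int
    ms2: int
    e_core: float
    h: np.ndarray
    eri: np.ndarray
    notation: str = CHEMISTS
    orbsym: np.ndarray = field(default=None)
    point_group: str = "C1"

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.eri = np.asarray(self.eri, dtype=float)
        if self.orbsym is None:
            self.orbsym = np.zeros(self.M, dtype=np.int64)
        self.orbsym = np.asarray(self.orbsym, dtype=np.int64)
        if self.h.shape != (self.M, self.M):
            raise ValueError(f"h has shape {self.h.shape}, expected {(self.M,)*2}")
        if self.eri.shape != (self.M,) * 4:
            raise ValueError(f"eri has shape {self.eri.shape}, expected {(self.M,)*4}")
        if self.orbsym.shape != (self.M,):
            raise ValueError("orbsym length must equal M")
        if self.notation not in (CHEMISTS, PHYSICISTS):
            raise ValueError(f"unknown notation {self.notation!r}")

    @property
    def n_alpha(self) -> int:
        return (self.n_elec + self.ms2) // 2

    @property
    def n_beta(self) -> int:
        return (self.n_elec - self.ms2) // 2

    def validate(self, tol: float = 1e-10) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if (self.n_elec + self.ms2) % 2 != 0:
            raise ValueError("n_elec and ms2 have mismatched parity")
        if self.M < max(self.n_alpha, self.n_beta):
            raise ValueError("fewer orbitals than electrons of one spin")
        if not np.allclose(self.h, self.h.T, atol=tol):
            raise ValueError("h is not symmetric")
        e = self.eri
        if self.notation == CHEMISTS:
            perms = [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]
        else:  # <pr|qs>: swap electrons, or transpose bra/ket (real orbitals)
            perms = [(1, 0, 3, 2), (2, 3, 0, 1), (3, 2, 1, 0)]
        for p in perms:
            if not np.allclose(e, e.transpose(p), atol=tol):
                raise ValueError(f"eri violates permutational symmetry {p}")
        order = _group_order(self.orbsym)
        if order & (order - 1):
            raise ValueError("irrep codes do not span a power-of-two group order")

    def copy(self) -> "SpinFreeIntegrals":
        return replace(self, h=self.h.copy(), eri=self.eri.copy(),
                       orbsym=self.orbsym.copy())


def _group_order(orbsym: np.ndarray) -> int:
    top = int(orbsym.max(initial=0))
    order = 1
    while order <= top:
        order *= 2
    return order


def restore_eri_symmetry(eri: np.ndarray, notation: str = CHEMISTS) -> np.ndarray:
    """Symmetrize a partially filled 4-index table over the 8-fold group."""
    out = eri.copy()
    if notation == CHEMISTS:
        gens = [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]
    else:
        gens = [(1, 0, 3, 2), (2, 3, 0, 1), (3, 2, 1, 0)]
    # closure of the generators (8 permutations); propagate max-abs entries
    for _ in range(3):
        for g in gens:
            t = out.transpose(g)
            out = np.where(np.abs(out) >= np.abs(t), out, t)
    return out


_NAMELIST_KEY = re.compile(r"([A-Za-z][A-Za-z0-9]*)\s*=")


def _parse_namelist(text: str) -> dict:
    body = text
    body = re.sub(r"&FCI", "", body, count=1, flags=re.IGNORECASE)
    keys = {}
    matches = list(_NAMELIST_KEY.finditer(body))
    for i, m in enumerate(matches):
        start = m.end()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(body)
        raw = body[start:end].replace(",", " ").split()
        keys[m.group(1).upper()] = raw
    return keys


def read_fcidump(path, orbsym_convention: str = "molpro",
                 point_group: str = "C1") -> SpinFreeIntegrals:
    """Read an FCIDUMP file into chemists'-notation integrals.

    Unlisted permutation-symmetric entries are filled in; indices become
    0-based in memory.  ``orbsym_convention`` is ``"molpro"`` (1-based codes,
    the on-disk default) or ``"xor"`` (0-based XOR codes as stored).
    """
    lines = Path(path).read_text().splitlines()
    header, data_start = [], None
    for ln, line in enumerate(lines):
        header.append(line)
        if re.search(r"&END|/\s*$", line, flags=re.IGNORECASE):
            data_start = ln + 1
            break
    if data_start is None:
        raise FcidumpFormatError(f"{path}: no &END terminating the namelist")
    keys = _parse_namelist("\n".join(header))
    for req in ("NORB", "NELEC"):
        if req not in keys:
            raise FcidumpFormatError(f"{path}: missing namelist key {req}")
    norb = int(keys["NORB"][0])
    nelec = int(keys["NELEC"][0])
    ms2 = int(keys["MS2"][0]) if keys.get("MS2") else 0
    if keys.get("ORBSYM"):
        orbsym = np.array([int(x) for x in keys["ORBSYM"]], dtype=np.int64)
        if orbsym.size != norb:
            raise FcidumpFormatError(f"{path}: ORBSYM has {orbsym.size} entries, "
                                     f"expected NORB={norb}")
    else:
        orbsym = np.ones(norb, dtype=np.int64)
    if orbsym_convention == "molpro":
        orbsym = orbsym - 1
    elif orbsym_convention != "xor":
        raise ValueError(f"unknown orbsym convention {orbsym_convention!r}")
    if orbsym.min(initial=0) < 0:
        raise FcidumpFormatError(f"{path}: negative irrep code after conversion")

    h = np.zeros((norb, norb))
    eri = np.zeros((norb,) * 4)
    seen_h, seen_eri = {}, {}
    e_core = 0.0
    for ln in range(data_start, len(lines)):
        parts = lines[ln].split()
        if not parts:
            continue
        if len(parts) != 5:
            raise FcidumpFormatError(f"{path}:{ln + 1}: expected 'value i j k l'")
        val = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise FcidumpFormatError(f"{path}:{ln + 1}: index {idx} outside "
                                         f"[0, NORB={norb}]")
        if i == j == k == l == 0:
            e_core = val
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise FcidumpFormatError(f"{path}:{ln + 1}: malformed record")
            key = (min(i, j), max(i, j))
            if key in seen_h and abs(seen_h[key] - val) > 1e-12:
                raise FcidumpFormatError(f"{path}:{ln + 1}: conflicting duplicate "
                                         f"h record for {key}")
            seen_h[key] = val
            h[i - 1, j - 1] = h[j - 1, i - 1] = val
        elif min(i, j, k, l) == 0:
            raise FcidumpFormatError(f"{path}:{ln + 1}: malformed record")
        else:
            key = _canonical_eri_key(i - 1, j - 1, k - 1, l - 1)
            if key in seen_eri and abs(seen_eri[key] - val) > 1e-12:
                raise FcidumpFormatError(f"{path}:{ln + 1}: conflicting duplicate "
                                         f"eri record for {key}")
            seen_eri[key] = val
            _set_eri8(eri, i - 1, j - 1, k - 1, l - 1, val)

    ints = SpinFreeIntegrals(M=norb, n_elec=nelec, ms2=ms2, e_core=e_core,
                             h=h, eri=eri, notation=CHEMISTS, orbsym=orbsym,
                             point_group=point_group)
    return ints


def _canonical_eri_key(p, q, r, s):
    a = (min(p, q), max(p, q))
    b = (min(r, s), max(r, s))
    return (a, b) if a <= b else (b, a)


def _set_eri8(eri, p, q, r, s, val):
    for (a, b) in ((p, q), (q, p)):
        for (c, d) in ((r, s), (s, r)):
            eri[a, b, c, d] = val
            eri[c, d, a, b] = val


def write_fcidump(ints: SpinFreeIntegrals, path, tol: float = 1e-12,
                  isym: int = 1) -> None:
    """Write chemists'-notation integrals as a deterministic FCIDUMP file.

    Only symmetry-unique entries with ``|value| > tol`` are emitted, eri
    records first, then h, then the core energy.
    """
    if ints.notation != CHEMISTS:
        raise ValueError("write_fcidump requires chemists' notation; "
                         "use convert_notation first")
    M = ints.M
    lines = [f"&FCI NORB={M},NELEC={ints.n_elec},MS2={ints.ms2},",
             "  ORBSYM=" + ",".join(str(int(s) + 1) for s in ints.orbsym) + ",",
             f"  ISYM={isym},",
             "&END"]
    emitted = set()
    for p in range(M):
        for q in range(p + 1):
            for r in range(p + 1):
                for s in range(r + 1):
                    key = _canonical_eri_key(p, q, r, s)
                    if key in emitted:
                        continue
                    emitted.add(key)
                    v = ints.eri[p, q, r, s]
                    if abs(v) > tol:
                        lines.append(f"{v:23.16e} {p+1:3d} {q+1:3d} "
                                     f"{r+1:3d} {s+1:3d}")
    for p in range(M):
        for q in range(p + 1):
            if abs(ints.h[p, q]) > tol:
                lines.append(f"{ints.h[p, q]:23.16e} {p+1:3d} {q+1:3d}   0   0")
    lines.append(f"{ints.e_core:23.16e}   0   0   0   0")
    Path(path).write_text("\n".join(lines) + "\n")


def convert_notation(ints: SpinFreeIntegrals, target: str) -> SpinFreeIntegrals:
    """Convert between chemists' ``(pq|rs)`` and physicists' ``<pr|qs>``.

    For real orbitals the map is the index permutation
    ``<pr|qs> = (pq|rs)``; applying it twice is the identity.
    """
    if target not in (CHEMISTS, PHYSICISTS):
        raise ValueError(f"unknown target notation {target!r}")
    if ints.notation == target:
        return ints.copy()
    out = ints.copy()
    # (p,q,r,s) -> (p,r,q,s) is its own inverse
    out.eri = np.ascontiguousarray(ints.eri.transpose(0, 2, 1, 3))
    out.notation = target
    return out


def fold_frozen_core(ints: SpinFreeIntegrals, frozen) -> SpinFreeIntegrals:
    """Fold doubly occupied frozen orbitals into an effective active space.

    Standard closed-shell folding: the frozen orbitals contribute a constant
    energy shift and a mean-field (Coulomb - half exchange) potential to the
    active one-electron integrals.  ``n_elec`` drops by 2 per frozen orbital.
    """
    frozen = sorted(set(int(f) for f in frozen))
    if not frozen:
        return ints.copy()
    if any(f < 0 or f >= ints.M for f in frozen):
        raise ValueError("frozen orbital index out of range")
    active = [p for p in range(ints.M) if p not in frozen]
    if ints.n_elec < 2 * len(frozen):
        raise ValueError("not enough electrons to doubly occupy frozen orbitals")

    chem = convert_notation(ints, CHEMISTS) if ints.notation != CHEMISTS else ints
    h, eri = chem.h, chem.eri
    e_core = chem.e_core
    for i in frozen:
        e_core += 2.0 * h[i, i]
        for j in frozen:
            e_core += 2.0 * eri[i, i, j, j] - eri[i, j, j, i]
    ix = np.ix_(active, active)
    h_act = h[ix].copy()
    for i in frozen:
        h_act += 2.0 * eri[np.ix_(active, active, [i], [i])][:, :, 0, 0]
        h_act -= eri[np.ix_(active, [i], [i], active)][:, 0, 0, :]
    eri_act = eri[np.ix_(active, active, active, active)].copy()

    out = SpinFreeIntegrals(
        M=len(active),
        n_elec=ints.n_elec - 2 * len(frozen),
        ms2=ints.ms2,
        e_core=e_core,
        h=h_act,
        eri=eri_act,
        notation=CHEMISTS,
        orbsym=ints.orbsym[active].copy(),
        point_group=ints.point_group,
    )
    if ints.notation == PHYSICISTS:
        out = convert_notation(out, PHYSICISTS)
    return out
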