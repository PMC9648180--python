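"""Slater-determinant wavefunction container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .determinants import Determinant

__all__ = ["WavefunctionSD", "save_state", "load_state"]


@dataclass
class WavefunctionSD:
    """Coefficients over an explicit determinant list.

    Determinants are kept sorted by the canonical key ``(alpha << M) | beta``
    so membership lookups are binary searches.  All determinants must share
    one (n_alpha, n_beta).
    """

    M: int
    alphas: np.ndarray
    betas: np.ndarray
    coeffs: np.ndarray

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=np.int64)
        self.betas = np.asarray(self.betas, dtype=np.int64)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not (len(self.alphas) == len(self.betas) == len(self.coeffs)):
            raise ValueError("alphas, betas, coeffs must have equal length")
        if len(self.alphas):
            na = Determinant(int(self.alphas[0]), int(self.betas[0]))
            n_a = na.alpha.bit_count()
            n_b = na.beta.bit_count()
            for a, b in zip(self.alphas, self.betas):
                if int(a).bit_count() != n_a or int(b).bit_count() != n_b:
                    raise ValueError("non-uniform electron counts")
        keys = self.keys()
        if np.any(np.diff(keys) <= 0):
            order = np.argsort(keys, kind="stable")
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate determinants")
            self.alphas = self.alphas[order]
            self.betas = self.betas[order]
            self.coeffs = self.coeffs[order]

    @classmethod
    def from_dict(cls, M: int, data: dict) -> "WavefunctionSD":
        """Build from a ``{(alpha, beta): coeff}`` mapping."""
        if not data:
            return cls(M, np.zeros(0, np.int64), np.zeros(0, np.int64),
                       np.zeros(0))
        items = sorted(data.items(), key=lambda kv: (kv[0][0] << M) | kv[0][1])
        a = np.array([k[0] for k, _ in items], dtype=np.int64)
        b = np.array([k[1] for k, _ in items], dtype=np.int64)
        c = np.array([v for _, v in items], dtype=float)
        return cls(M, a, b, c)

    def to_dict(self) -> dict:
        return {(int(a), int(b)): float(c)
                for a, b, c in zip(self.alphas, self.betas, self.coeffs)}

    def keys(self) -> np.ndarray:
        return (self.alphas.astype(object) << self.M) | self.betas.astype(object)

    def __len__(self) -> int:
        return len(self.coeffs)

    def __iter__(self):
        for a, b, c in zip(self.alphas, self.betas, self.coeffs):
            yield Determinant(int(a), int(b)), float(c)

    @property
    def n_alpha(self) -> int:
        return int(self.alphas[0]).bit_count() if len(self.alphas) else 0

    @property
    def n_beta(self) -> int:
        return int(self.betas[0]).bit_count() if len(self.betas) else 0

    @property
    def n_elec(self) -> int:
        return self.n_alpha + self.n_beta

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.coeffs))

    def normalized(self) -> "WavefunctionSD":
        n = self.norm
        if n == 0.0:
            raise ValueError("zero-norm wavefunction")
        return WavefunctionSD(self.M, self.alphas.copy(), self.betas.copy(),
                              self.coeffs / n)

    def index_of(self, det: Determinant) -> int:
        """Index of a determinant, or -1 if absent (binary search)."""
        key = (det.alpha << self.M) | det.beta
        keys = self.keys()
        pos = int(np.searchsorted(keys, key))
        if pos < len(keys) and keys[pos] == key:
            return pos
        return -1

    def lookup(self, det: Determinant) -> float:
        i = self.index_of(det)
        return float(self.coeffs[i]) if i >= 0 else 0.0


def save_state(wfn: WavefunctionSD, path) -> None:
    """Write a (bitstring, bitstring, coefficient) state table.

    Bitstrings are printed most-significant orbital first, so the rightmost
    character is orbital 0.
    """
    with open(path, "w") as f:
        f.write(f"# state M={wfn.M} n_det={len(wfn)}\n")
        for det, c in wfn:
            f.write(f"{det.alpha:0{wfn.M}b} {det.beta:0{wfn.M}b} "
                    f"{c:.16e}\n")


def load_state(path) -> WavefunctionSD:
    with open(path) as f:
        header = f.readline().split()
        meta = dict(kv.split("=") for kv in header if "=" in kv)
        M = int(meta["M"])
        data = {}
        for line in f:
            a, b, c = line.split()
            data[(int(a, 2), int(b, 2))] = float(c)
    return WavefunctionSD.from_dict(M, data)
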