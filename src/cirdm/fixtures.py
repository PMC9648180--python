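"""Deterministic FCIDUMP fixture generators (no downloads needed)."""

from __future__ import annotations

import numpy as np

from .integrals import SpinFreeIntegrals, write_fcidump

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("random-hermitian", "two-orbital-pair", "hubbard-like",
                 "named-molecule")


def make_fixture(kind: str, seed: int, path=None, **params):
    """Build a toy integral set; optionally write it as an FCIDUMP file.

    Kinds: ``random-hermitian`` (8-fold-symmetric random integrals),
    ``two-orbital-pair`` (closed-shell 2x2 pairing model solvable by hand),
    ``hubbard-like`` (open chain, on-site repulsion), and ``named-molecule``
    (delegates to the pyscf provider adapter when available).
    """
    if kind == "random-hermitian":
        ints = _random_hermitian(seed, **params)
    elif kind == "two-orbital-pair":
        ints = _two_orbital_pair(**params)
    elif kind == "hubbard-like":
        ints = _hubbard_like(**params)
    elif kind == "named-molecule":
        from . import provider
        ints = provider.molecule_integrals(**params)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    if path is not None:
        write_fcidump(ints, path)
    return ints


def _random_hermitian(seed, M=6, n_elec=4, ms2=0, scale=0.2, orbsym=None):
    rng = np.random.default_rng(seed)
    h = rng.standard_normal((M, M)) * scale
    h = (h + h.T) / 2
    np.fill_diagonal(h, np.sort(rng.standard_normal(M)) - 1.0)
    eri = rng.standard_normal((M,) * 4) * scale
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
        eri = (eri + eri.transpose(perm)) / 2
    return SpinFreeIntegrals(M=M, n_elec=n_elec, ms2=ms2,
                             e_core=float(rng.standard_normal()),
                             h=h, eri=eri, notation="chemists",
                             orbsym=orbsym)


def _two_orbital_pair(e1=-1.0, e2=-0.5, u=0.3, k=0.1):
    """Two-level closed-shell pairing model.

    Only (11|11) = (22|22) = u and (12|12) = k are nonzero, so the Ms=0
    singlet problem block-diagonalizes and the ground state is the lower
    eigenvalue of [[2 e1 + u, k], [k, 2 e2 + u]].
    """
    h = np.diag([e1, e2]).astype(float)
    eri = np.zeros((2, 2, 2, 2))
    eri[0, 0, 0, 0] = eri[1, 1, 1, 1] = u
    for (p, q, r, s) in [(0, 1, 0, 1), (1, 0, 0, 1), (0, 1, 1, 0),
                         (1, 0, 1, 0)]:
        eri[p, q, r, s] = k
    return SpinFreeIntegrals(M=2, n_elec=2, ms2=0, e_core=0.0, h=h, eri=eri,
                             notation="chemists")


def _hubbard_like(L=4, t=1.0, u=2.0, n_elec=None, ms2=0):
    """Open Hubbard chain in the site basis: hopping -t, on-site U."""
    if n_elec is None:
        n_elec = L - L % 2
    h = np.zeros((L, L))
    for i in range(L - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    eri = np.zeros((L,) * 4)
    for i in range(L):
        eri[i, i, i, i] = u
    return SpinFreeIntegrals(M=L, n_elec=n_elec, ms2=ms2, e_core=0.0,
                             h=h, eri=eri, notation="chemists")
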