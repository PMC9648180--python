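"""String-driven FCI: sigma builds, Davidson diagonalization, solver.

The CI vector lives on the alpha x beta string grid.  The Hamiltonian is
applied without ever forming it: same-spin contributions come from
precomputed per-channel sparse matrices (block-diagonal over irreps),
and mixed-spin doubles from the generalized single-excitation tables
contracted against the two-electron integrals one alpha string at a time
(a small dense matmul per string, restricted to symmetry-allowed blocks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .determinants import Determinant
from .integrals import PHYSICISTS, SpinFreeIntegrals, convert_notation
from .stringspace import StringSpace, enumerate_strings
from .wavefunction import WavefunctionSD

__all__ = ["CIVector", "FciProblem", "sigma", "davidson", "fci_solve"]


@dataclass
class CIVector:
    """Coefficients over the alpha x beta determinant grid."""

    space_a: StringSpace
    space_b: StringSpace
    C: np.ndarray
    ms2: int
    target_irrep: int | None = None
    _mask: np.ndarray = field(default=None, repr=False)

    @property
    def shape(self):
        return self.C.shape

    @property
    def allowed_mask(self) -> np.ndarray:
        """Boolean grid of symmetry-allowed determinants."""
        if self._mask is None:
            if self.target_irrep is None:
                self._mask = np.ones(self.C.shape, dtype=bool)
            else:
                ga = self.space_a.irreps[:, None]
                gb = self.space_b.irreps[None, :]
                self._mask = (ga ^ gb) == self.target_irrep
        return self._mask

    def coefficients(self) -> np.ndarray:
        """Flat coefficient vector over the allowed determinants."""
        return self.C[self.allowed_mask]

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.C))

    def as_wavefunction(self, tol: float = 0.0) -> WavefunctionSD:
        ia, ib = np.nonzero(np.abs(self.C) > tol if tol > 0
                            else self.C != 0.0)
        return WavefunctionSD(self.space_a.M,
                              self.space_a.strings[ia],
                              self.space_b.strings[ib],
                              self.C[ia, ib])


class FciProblem:
    """Cached machinery for one (integrals, spaces, target irrep) problem."""

    def __init__(self, ints: SpinFreeIntegrals, space_a: StringSpace,
                 space_b: StringSpace, target_irrep: int | None = None):
        if ints.notation != PHYSICISTS:
            ints = convert_notation(ints, PHYSICISTS)
        self.ints = ints
        self.space_a = space_a
        self.space_b = space_b
        self.target = target_irrep
        M = ints.M
        self.M = M
        self.order = max(space_a.group_order, space_b.group_order)

        self.Ka = space_a.same_spin_h(ints)
        self.Kb = space_b.same_spin_h(ints)
        if target_irrep is not None:
            self._Ka_blocks = [self.Ka[space_a.block(g), space_a.block(g)]
                               for g in range(self.order)]
            self._Kb_blocks = [self.Kb[space_b.block(g), space_b.block(g)]
                               for g in range(self.order)]

        # mixed coupling (pq|kl) = <pk|ql>, kl axis sorted by pair irrep
        V = ints.eri.transpose(0, 2, 1, 3).reshape(M * M, M * M)
        g_pair = (ints.orbsym[:, None] ^ ints.orbsym[None, :]).reshape(-1)
        self.klorder = np.lexsort((np.arange(M * M), g_pair))
        self.klpos = np.empty(M * M, dtype=np.int64)
        self.klpos[self.klorder] = np.arange(M * M)
        self.kl_offsets = np.searchsorted(g_pair[self.klorder],
                                          np.arange(self.order + 1))
        self.Vp = np.ascontiguousarray(V[:, self.klorder])

        self.tJa, tPQa, self.tSa = space_a.singles
        self.tPQa = tPQa
        self.tJb, tPQb, self.tSb = space_b.singles
        self.tKLb = self.klpos[tPQb] if tPQb.size else tPQb
        self._G = np.empty((M * M, len(space_b)))

        # Davidson bookkeeping over the allowed determinants
        if target_irrep is None:
            mask = np.ones((len(space_a), len(space_b)), dtype=bool)
        else:
            mask = (space_a.irreps[:, None] ^ space_b.irreps[None, :]
                    ) == target_irrep
        self.mask = mask
        self.flat_idx = np.flatnonzero(mask.ravel())
        self.dim = len(self.flat_idx)

    # -- grid <-> compressed -------------------------------------------------
    def expand(self, x: np.ndarray) -> np.ndarray:
        C = np.zeros(self.mask.size)
        C[self.flat_idx] = x
        return C.reshape(self.mask.shape)

    def compress(self, C: np.ndarray) -> np.ndarray:
        return C.ravel()[self.flat_idx]

    # -- Hamiltonian application --------------------------------------------
    def sigma_grid(self, C: np.ndarray) -> np.ndarray:
        """H @ C on the full grid (no dense H is ever formed)."""
        S = np.zeros_like(C)
        if self.target is None:
            S += self.Ka @ C
            S += (self.Kb @ C.T).T
        else:
            for g in range(self.order):
                ra = self.space_a.block(g)
                cb = self.space_b.block(self.target ^ g)
                if ra.stop > ra.start and cb.stop > cb.start:
                    S[ra, cb] += self._Ka_blocks[g] @ C[ra, cb]
            for g in range(self.order):
                cb = self.space_b.block(g)
                ra = self.space_a.block(self.target ^ g)
                if ra.stop > ra.start and cb.stop > cb.start:
                    S[ra, cb] += C[ra, cb] @ self._Kb_blocks[g].T
        self._sigma_mixed(C, S)
        return S

    def _sigma_mixed(self, C: np.ndarray, S: np.ndarray) -> None:
        if self.tPQa.size == 0 or self.tJb.size == 0:
            return
        G = self._G
        nb = len(self.space_b)
        ntb = self.tJb.shape[1]
        for Ia in range(len(self.space_a)):
            D = self.tSa[Ia][:, None] * C[self.tJa[Ia], :]
            Esel = self.Vp[self.tPQa[Ia], :]
            if self.target is None:
                np.dot(Esel.T, D, out=G)
                idx = slice(0, nb)
            else:
                g_out = self.target ^ int(self.space_a.irreps[Ia])
                for gp in range(self.order):
                    cb = self.space_b.block(gp)
                    if cb.stop == cb.start:
                        continue
                    gk = g_out ^ gp
                    k0, k1 = self.kl_offsets[gk], self.kl_offsets[gk + 1]
                    if k1 > k0:
                        G[k0:k1, cb] = Esel[:, k0:k1].T @ D[:, cb]
                idx = self.space_b.block(g_out)
            if idx.stop == idx.start:
                continue
            contrib = np.einsum(
                "it,it->i",
                G[self.tKLb[idx].ravel(),
                  self.tJb[idx].ravel()].reshape(-1, ntb),
                self.tSb[idx])
            S[Ia, idx] += contrib

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self.compress(self.sigma_grid(self.expand(x)))

    def diagonal(self) -> np.ndarray:
        """H diagonal over the allowed determinants (preconditioner)."""
        da = self.space_a.diag(self.ints)
        db = self.space_b.diag(self.ints)
        M = self.M
        Oa = _occupancy(self.space_a)
        Ob = _occupancy(self.space_b)
        Jmat = np.einsum("pqpq->pq", self.ints.eri)
        grid = da[:, None] + db[None, :] + Oa @ Jmat @ Ob.T
        return self.compress(grid)


def _occupancy(space: StringSpace) -> np.ndarray:
    O = np.zeros((len(space), space.M))
    occ = space.occ_lists
    if occ.shape[1]:
        np.put_along_axis(O, occ, 1.0, axis=1)
    return O


def sigma(b: CIVector, ints: SpinFreeIntegrals) -> CIVector:
    """Apply the Hamiltonian to a CI vector: d = H b."""
    prob = FciProblem(ints, b.space_a, b.space_b, b.target_irrep)
    if b.C.shape != (len(b.space_a), len(b.space_b)):
        raise ValueError("CI vector shape does not match its spaces")
    return CIVector(b.space_a, b.space_b, prob.sigma_grid(b.C), b.ms2,
                    b.target_irrep)


def davidson(apply_H, dim: int, n_roots: int, diag: np.ndarray, guess=None,
             tol: float = 1e-9, max_iter: int = 200, max_subspace: int = None,
             verbose: bool = False):
    """Lowest eigenpairs of a symmetric operator by block Davidson.

    ``apply_H`` maps a 1-D vector to H @ v; ``diag`` preconditions the
    residuals.  Returns (eigenvalues, eigenvectors, info) where info holds
    residual norms, iteration count, and a convergence flag.  A warm-start
    ``guess`` of shape (dim,) or (dim, k) is honored.
    """
    if n_roots > dim:
        raise ValueError("more roots than dimensions")
    if max_subspace is None:
        max_subspace = min(dim, max(6 * n_roots + 12, 24))
    diag = np.asarray(diag, dtype=float)

    if dim <= max(6 * n_roots, 120):
        # subspace smaller than the overhead is worth: build H densely
        H = np.column_stack([apply_H(e) for e in np.eye(dim)])
        vals, vecs = np.linalg.eigh((H + H.T) / 2)
        info = {"iterations": 0, "residual_norms": np.zeros(n_roots),
                "converged": True}
        return vals[:n_roots], vecs[:, :n_roots], info

    if guess is None:
        V = np.zeros((dim, n_roots))
        order = np.argsort(diag, kind="stable")
        for k in range(n_roots):
            V[order[k], k] = 1.0
    else:
        V = np.atleast_2d(np.asarray(guess, dtype=float).T).T.copy()
        if V.shape[0] != dim:
            raise ValueError("guess has wrong dimension")
        while V.shape[1] < n_roots:
            e = np.zeros((dim, 1))
            e[np.argsort(diag)[V.shape[1]], 0] = 1.0
            V = np.hstack([V, e])
    V = _orthonormalize(V)
    W = np.column_stack([apply_H(V[:, i]) for i in range(V.shape[1])])

    theta = np.zeros(n_roots)
    X = R = None
    res_norms = np.full(n_roots, np.inf)
    for it in range(1, max_iter + 1):
        Hs = V.T @ W
        vals, Y = np.linalg.eigh((Hs + Hs.T) / 2)
        theta = vals[:n_roots]
        X = V @ Y[:, :n_roots]
        WX = W @ Y[:, :n_roots]
        R = WX - X * theta
        res_norms = np.linalg.norm(R, axis=0)
        if verbose:
            print(f"davidson it {it:3d} dim {V.shape[1]:4d} "
                  f"E {theta} |r| {res_norms}")
        if np.all(res_norms <= tol):
            info = {"iterations": it, "residual_norms": res_norms,
                    "converged": True}
            return theta, X, info
        if V.shape[1] + n_roots > max_subspace:
            # thick restart: keep a few extra Ritz vectors beyond the roots
            m = min(2 * n_roots + 2, V.shape[1])
            V = V @ Y[:, :m]
            W = W @ Y[:, :m]
            V, rmat = np.linalg.qr(V)
            W = W @ _inv_upper(rmat)
        new_dirs = []
        for k in range(n_roots):
            if res_norms[k] <= tol:
                continue
            denom = diag - theta[k]
            denom = np.where(np.abs(denom) < 1e-8,
                             np.copysign(1e-8, denom), denom)
            # Olsen correction: keep the update orthogonal to the Ritz vector
            y1 = R[:, k] / denom
            y2 = X[:, k] / denom
            xy2 = X[:, k] @ y2
            eps = (X[:, k] @ y1) / xy2 if abs(xy2) > 1e-14 else 0.0
            new_dirs.append(y1 - eps * y2)
        T = np.column_stack(new_dirs)
        T = T - V @ (V.T @ T)
        T = T - V @ (V.T @ T)
        keep = np.linalg.norm(T, axis=0) > 1e-10
        if not np.any(keep):
            break
        T = _orthonormalize(T[:, keep])
        V = np.hstack([V, T])
        W = np.hstack([W, np.column_stack(
            [apply_H(T[:, i]) for i in range(T.shape[1])])])

    warnings.warn(f"Davidson did not converge in {max_iter} iterations; "
                  f"residual norms {res_norms}")
    info = {"iterations": max_iter, "residual_norms": res_norms,
            "converged": False}
    return theta, X, info


def _orthonormalize(V: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(V)
    keep = np.abs(np.diag(R)) > 1e-12
    return Q[:, keep]


def _inv_upper(R: np.ndarray) -> np.ndarray:
    return np.linalg.solve(R, np.eye(R.shape[0]))


def fci_solve(ints: SpinFreeIntegrals, target_irrep: int | None = None,
              ms2: int | None = None, n_roots: int = 1, tol: float = 1e-9,
              max_iter: int = 200, guess=None, guess_dim: int = 400,
              max_subspace: int = None, verbose: bool = False):
    """Variational eigenstates of the (symmetry, Ms)-restricted space.

    Returns a list of (energy, CIVector) pairs in ascending energy order.
    """
    if ms2 is None:
        ms2 = ints.ms2
    if (ints.n_elec + ms2) % 2:
        raise ValueError("ms2 parity incompatible with electron count")
    n_a = (ints.n_elec + ms2) // 2
    n_b = (ints.n_elec - ms2) // 2
    ints_p = convert_notation(ints, PHYSICISTS)
    space_a = enumerate_strings(ints.M, n_a, ints.orbsym)
    space_b = (space_a if n_b == n_a
               else enumerate_strings(ints.M, n_b, ints.orbsym))
    prob = FciProblem(ints_p, space_a, space_b, target_irrep)
    if prob.dim == 0:
        raise ValueError("no determinant of the requested irrep exists")

    diag = prob.diagonal()
    if guess is None and prob.dim > 120:
        guess = _guess_from_diag(prob, diag, n_roots, guess_dim, ints_p)
    theta, X, info = davidson(prob.matvec, prob.dim, n_roots, diag,
                              guess=guess, tol=tol, max_iter=max_iter,
                              max_subspace=max_subspace, verbose=verbose)
    out = []
    for k in range(n_roots):
        vec = CIVector(space_a, space_b, prob.expand(X[:, k]), ms2,
                       target_irrep)
        out.append((float(theta[k] + ints.e_core), vec))
    return out


def _guess_from_diag(prob: FciProblem, diag: np.ndarray, n_roots: int,
                     guess_dim: int, ints_p: SpinFreeIntegrals) -> np.ndarray:
    """Diagonalize H in the lowest-diagonal determinant subset."""
    k = min(max(guess_dim, 4 * n_roots), prob.dim)
    sel = np.argsort(diag, kind="stable")[:k]
    flat = prob.flat_idx[sel]
    nb = len(prob.space_b)
    alphas = prob.space_a.strings[flat // nb]
    betas = prob.space_b.strings[flat % nb]
    H = _kernels.h_dense(alphas, betas, ints_p.h, ints_p.eri)
    _, vecs = np.linalg.eigh(H)
    G = np.zeros((prob.dim, n_roots))
    G[sel, :] = vecs[:, :n_roots]
    return G


def reference_determinant(ints: SpinFreeIntegrals,
                          ms2: int | None = None) -> Determinant:
    """Aufbau determinant: lowest-index orbitals per spin channel."""
    if ms2 is None:
        ms2 = ints.ms2
    n_a = (ints.n_elec + ms2) // 2
    n_b = (ints.n_elec - ms2) // 2
    return Determinant((1 << n_a) - 1, (1 << n_b) - 1)
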