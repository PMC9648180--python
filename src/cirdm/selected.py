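"""Selected CI: stochastic configuration selection (MCCI) and truncated CI.

The MCCI loop repeatedly (i) augments the configuration set with random
single/double substitutions of randomly chosen members, (ii) updates the
stored subspace Hamiltonian incrementally, (iii) diagonalizes with a
warm start from the previous coefficients, and (iv) prunes newly added
configurations whose absolute coefficient falls below the cutoff c_min
(every tenth iteration all configurations except the protected reference
are eligible).  Convergence is declared when the energy change between
consecutive full-prune checkpoints stays below a threshold.

Randomness is counter-based: iteration t draws from Philox(key=(seed, t)),
so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from . import _kernels
from .determinants import Determinant, string_irrep
from .fci import davidson, reference_determinant
from .integrals import PHYSICISTS, SpinFreeIntegrals, convert_notation
from .wavefunction import WavefunctionSD

__all__ = ["MCCIState", "MCCIOptions", "truncated_ci_solve", "mcci_augment",
           "subspace_hamiltonian_update", "mcci_prune", "mcci_run"]


@dataclass
class MCCIOptions:
    n_add: int | None = None          # default max(50, current size)
    max_iter: int = 200
    full_prune_every: int = 10
    conv_threshold: float = 5e-4      # hartree, between full-prune checkpoints
    conv_window: int = 2              # consecutive converged checkpoints
    davidson_tol: float = 1e-9


@dataclass
class MCCIState:
    """Configuration set, stored subspace Hamiltonian, and bookkeeping."""

    M: int
    ints: SpinFreeIntegrals
    alphas: np.ndarray
    betas: np.ndarray
    new_flags: np.ndarray
    H_sub: np.ndarray
    c_min: float
    coeffs: np.ndarray = None          # (n_configs, n_roots)
    energies: np.ndarray = None
    iteration: int = 0
    rng_seed: int = 0
    energy_history: list = field(default_factory=list)
    target_irrep: int | None = None

    def __len__(self):
        return len(self.alphas)

    def keys(self) -> set:
        return {(int(a), int(b)) for a, b in zip(self.alphas, self.betas)}

    def diagonalize(self, n_roots: int = 1, tol: float = 1e-9) -> None:
        n = len(self)
        H = self.H_sub
        if n <= 600:
            vals, vecs = np.linalg.eigh(H)
            self.energies = vals[:n_roots]
            self.coeffs = vecs[:, :n_roots]
        else:
            guess = None
            if self.coeffs is not None and self.coeffs.shape[0] == n:
                guess = self.coeffs
            vals, vecs, _ = davidson(lambda x: H @ x, n, n_roots,
                                     np.diag(H), guess=guess, tol=tol)
            self.energies = vals
            self.coeffs = vecs

    def wavefunction(self, root: int = 0) -> WavefunctionSD:
        wfn = WavefunctionSD(self.M, self.alphas.copy(), self.betas.copy(),
                             self.coeffs[:, root].copy())
        return wfn.normalized()


def _allowed(det: Determinant, orbsym, target_irrep) -> bool:
    if target_irrep is None:
        return True
    return (string_irrep(det.alpha, orbsym)
            ^ string_irrep(det.beta, orbsym)) == target_irrep


def _random_substitution(det: Determinant, M: int, rng) -> Determinant | None:
    """One random single or double substitution of a determinant."""
    occ_a = [p for p in range(M) if (det.alpha >> p) & 1]
    occ_b = [p for p in range(M) if (det.beta >> p) & 1]
    virt_a = [p for p in range(M) if not (det.alpha >> p) & 1]
    virt_b = [p for p in range(M) if not (det.beta >> p) & 1]

    def single(bits, occ, virt):
        if not occ or not virt:
            return None
        h = occ[rng.integers(len(occ))]
        p = virt[rng.integers(len(virt))]
        return (bits ^ (1 << h)) | (1 << p)

    kind = rng.integers(5)  # 0 aS, 1 bS, 2 aaD, 3 bbD, 4 abD
    a, b = det.alpha, det.beta
    if kind == 0:
        a = single(a, occ_a, virt_a)
    elif kind == 1:
        b = single(b, occ_b, virt_b)
    elif kind == 2:
        a = single(a, occ_a, virt_a)
        if a is not None:
            occ2 = [p for p in range(M) if (a >> p) & 1]
            virt2 = [p for p in range(M) if not (a >> p) & 1]
            a = single(a, occ2, virt2)
    elif kind == 3:
        b = single(b, occ_b, virt_b)
        if b is not None:
            occ2 = [p for p in range(M) if (b >> p) & 1]
            virt2 = [p for p in range(M) if not (b >> p) & 1]
            b = single(b, occ2, virt2)
    else:
        a = single(a, occ_a, virt_a)
        b = single(b, occ_b, virt_b)
    if a is None or b is None:
        return None
    cand = Determinant(a, b)
    return None if cand == det else cand


def mcci_augment(state: MCCIState, n_add: int, rng) -> MCCIState:
    """Add up to ``n_add`` distinct allowed random substitutions.

    Duplicates and symmetry/Ms-forbidden candidates are skipped and redrawn;
    a bounded number of attempts keeps saturated spaces from spinning.
    """
    if n_add < 1:
        raise ValueError("n_add must be >= 1")
    existing = state.keys()
    added_a, added_b = [], []
    n = len(state)
    attempts = 0
    while len(added_a) < n_add and attempts < 50 * n_add:
        attempts += 1
        i = int(rng.integers(n))
        cand = _random_substitution(
            Determinant(int(state.alphas[i]), int(state.betas[i])),
            state.M, rng)
        if cand is None:
            continue
        key = (cand.alpha, cand.beta)
        if key in existing:
            continue
        if not _allowed(cand, state.ints.orbsym, state.target_irrep):
            continue
        existing.add(key)
        added_a.append(cand.alpha)
        added_b.append(cand.beta)
    if not added_a:
        return state
    state = replace(
        state,
        alphas=np.concatenate([state.alphas, np.array(added_a, np.int64)]),
        betas=np.concatenate([state.betas, np.array(added_b, np.int64)]),
        new_flags=np.concatenate([state.new_flags,
                                  np.ones(len(added_a), bool)]),
    )
    return subspace_hamiltonian_update(
        state, added=list(range(len(state) - len(added_a), len(state))),
        removed=[])


def subspace_hamiltonian_update(state: MCCIState, added, removed
                                ) -> MCCIState:
    """Incrementally maintain H_sub: only touched rows/columns change."""
    H = state.H_sub
    n_old = H.shape[0]
    if removed:
        for r in removed:
            if r < 0 or r >= n_old:
                raise ValueError(f"unknown configuration index {r}")
        keep = np.setdiff1d(np.arange(n_old), np.asarray(removed))
        H = H[np.ix_(keep, keep)]
    n_new = len(state)
    if added:
        grown = np.zeros((n_new, n_new))
        grown[:H.shape[0], :H.shape[1]] = H
        rows = _kernels.h_rows(state.alphas, state.betas,
                               np.asarray(added, np.int64),
                               state.ints.h, state.ints.eri)
        for k, i in enumerate(added):
            grown[i, :] = rows[k]
            grown[:, i] = rows[k]
        H = grown
    return replace(state, H_sub=H)


def mcci_prune(state: MCCIState, full: bool = False) -> MCCIState:
    """Drop configs below the cutoff (new-only, or all except reference)."""
    if state.coeffs is None:
        raise ValueError("diagonalize before pruning")
    cmax = np.max(np.abs(state.coeffs), axis=1)
    eligible = np.ones(len(state), bool) if full else state.new_flags.copy()
    eligible[0] = False  # the reference is never deletable
    drop = np.flatnonzero(eligible & (cmax < state.c_min))
    keep = np.setdiff1d(np.arange(len(state)), drop)
    new_state = replace(
        state,
        alphas=state.alphas[keep],
        betas=state.betas[keep],
        new_flags=np.zeros(len(keep), bool),
        coeffs=state.coeffs[keep, :] if state.coeffs is not None else None,
    )
    return subspace_hamiltonian_update(new_state, added=[],
                                       removed=list(drop))


def _initial_state(ints, c_min, target_irrep, ms2, seed) -> MCCIState:
    ref = reference_determinant(ints, ms2)
    if not _allowed(ref, ints.orbsym, target_irrep):
        raise ValueError("aufbau reference determinant has the wrong irrep; "
                         "choose the matching target or reorder orbitals")
    state = MCCIState(
        M=ints.M, ints=ints,
        alphas=np.array([ref.alpha], np.int64),
        betas=np.array([ref.beta], np.int64),
        new_flags=np.zeros(1, bool),
        H_sub=np.zeros((0, 0)),
        c_min=c_min, rng_seed=seed, target_irrep=target_irrep)
    return subspace_hamiltonian_update(state, added=[0], removed=[])


def mcci_run(ints: SpinFreeIntegrals, c_min: float,
             target_irrep: int | None = None, ms2: int | None = None,
             n_roots: int = 1, seed: int = 0,
             opts: MCCIOptions | None = None):
    """Run the MCCI loop; returns (wavefunction, energy_history, state).

    ``energy_history`` holds (iteration, n_configs, energies) after each
    post-prune diagonalization.  Non-convergence returns the best state
    with a warning.
    """
    opts = opts or MCCIOptions()
    if ms2 is None:
        ms2 = ints.ms2
    ints_p = convert_notation(ints, PHYSICISTS)
    state = _initial_state(ints_p, c_min, target_irrep, ms2, seed)
    checkpoint_energy = None
    converged_checkpoints = 0
    for it in range(1, opts.max_iter + 1):
        state.iteration = it
        rng = np.random.Generator(np.random.Philox(key=[seed, it]))
        n_add = opts.n_add or max(50, len(state))
        state = mcci_augment(state, n_add, rng)
        state.diagonalize(n_roots, opts.davidson_tol)
        full = (it % opts.full_prune_every == 0)
        state = mcci_prune(state, full=full)
        state.diagonalize(n_roots, opts.davidson_tol)
        e = state.energies + ints.e_core
        state.energy_history.append((it, len(state), e.copy()))
        if full:
            if checkpoint_energy is not None:
                if abs(e[0] - checkpoint_energy) < opts.conv_threshold:
                    converged_checkpoints += 1
                else:
                    converged_checkpoints = 0
            checkpoint_energy = e[0]
            if converged_checkpoints >= opts.conv_window:
                return state.wavefunction(), state.energy_history, state
    import warnings
    warnings.warn(f"MCCI did not converge within {opts.max_iter} iterations")
    return state.wavefunction(), state.energy_history, state


# ---------------------------------------------------------------------------
# truncated CI
# ---------------------------------------------------------------------------

def _strings_up_to_level(M, ref_bits, n, level):
    occ = [p for p in range(M) if (ref_bits >> p) & 1]
    virt = [p for p in range(M) if not (ref_bits >> p) & 1]
    out = []
    for lev in range(0, min(level, n, len(virt)) + 1):
        for holes in combinations(occ, lev):
            removed = ref_bits
            for h in holes:
                removed ^= 1 << h
            for parts in combinations(virt, lev):
                bits = removed
                for p in parts:
                    bits |= 1 << p
                out.append((bits, lev))
    return out


def truncated_ci_solve(ints: SpinFreeIntegrals, level: int,
                       target_irrep: int | None = None,
                       ms2: int | None = None, n_roots: int = 1,
                       tol: float = 1e-9):
    """Variational CI in the <= level substitution space from the reference.

    Returns a list of (energy, WavefunctionSD), ascending.  CI(2) is CISD;
    level >= N_e reproduces FCI.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if ms2 is None:
        ms2 = ints.ms2
    ints_p = convert_notation(ints, PHYSICISTS)
    ref = reference_determinant(ints, ms2)
    sa = _strings_up_to_level(ints.M, ref.alpha, ref.alpha.bit_count(), level)
    sb = _strings_up_to_level(ints.M, ref.beta, ref.beta.bit_count(), level)
    ga = {bits: string_irrep(bits, ints.orbsym) for bits, _ in sa}
    gb = {bits: string_irrep(bits, ints.orbsym) for bits, _ in sb}
    alphas, betas = [], []
    for abits, la in sa:
        for bbits, lb in sb:
            if la + lb > level:
                continue
            if (target_irrep is not None
                    and (ga[abits] ^ gb[bbits]) != target_irrep):
                continue
            alphas.append(abits)
            betas.append(bbits)
    if not alphas:
        raise ValueError("empty truncated CI space")
    alphas = np.array(alphas, np.int64)
    betas = np.array(betas, np.int64)
    order = np.argsort((alphas.astype(object) << ints.M) | betas.astype(object),
                       kind="stable")
    alphas, betas = alphas[order], betas[order]
    n = len(alphas)
    if n > 20000:
        raise ValueError(f"truncated space of {n} determinants is too large "
                         "for the dense subspace solver")
    H = _kernels.h_dense(alphas, betas, ints_p.h, ints_p.eri)
    if n <= 1500:
        vals, vecs = np.linalg.eigh(H)
        vals, vecs = vals[:n_roots], vecs[:, :n_roots]
    else:
        vals, vecs, _ = davidson(lambda x: H @ x, n, n_roots, np.diag(H),
                                 tol=tol)
    out = []
    for k in range(n_roots):
        wfn = WavefunctionSD(ints.M, alphas, betas, vecs[:, k])
        out.append((float(vals[k] + ints.e_core), wfn.normalized()))
    return out
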