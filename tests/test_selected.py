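import numpy as np
import pytest

from cirdm import _kernels
from cirdm.determinants import excitation_degree, string_irrep, Determinant
from cirdm.fci import fci_solve, reference_determinant
from cirdm.fixtures import make_fixture
from cirdm.integrals import PHYSICISTS, convert_notation
from cirdm.selected import (MCCIOptions, mcci_augment, mcci_prune,
                            mcci_run, subspace_hamiltonian_update,
                            truncated_ci_solve)


@pytest.fixture(scope="module")
def ints5():
    return make_fixture("random-hermitian", 11, M=5, n_elec=4)


@pytest.fixture(scope="module")
def e_fci5(ints5):
    return fci_solve(ints5, n_roots=1, tol=1e-11)[0][0]


def _fresh_state(ints, c_min=0.0, target=None, seed=0):
    from cirdm.selected import _initial_state
    return _initial_state(convert_notation(ints, PHYSICISTS), c_min, target,
                          ints.ms2, seed)


def test_cisd_complete_for_two_electrons():
    ints = make_fixture("random-hermitian", 5, M=4, n_elec=2)
    e_ci = truncated_ci_solve(ints, 2)[0][0]
    e_fci = fci_solve(ints, n_roots=1, tol=1e-11)[0][0]
    assert e_ci == pytest.approx(e_fci, abs=1e-10)


def test_level_nelec_equals_fci(ints5, e_fci5):
    e_ci = truncated_ci_solve(ints5, 4)[0][0]
    assert e_ci == pytest.approx(e_fci5, abs=1e-9)


def test_truncated_monotone(ints5, e_fci5):
    energies = [truncated_ci_solve(ints5, lev)[0][0] for lev in (1, 2, 3, 4)]
    for a, b in zip(energies, energies[1:]):
        assert b <= a + 1e-10
    assert all(e >= e_fci5 - 1e-10 for e in energies)


def test_truncated_empty_space_error():
    ints = make_fixture("random-hermitian", 2, M=4, n_elec=2,
                        orbsym=[0, 0, 0, 0])
    with pytest.raises(ValueError):
        truncated_ci_solve(ints, 1, target_irrep=3)


def test_augment_deterministic(ints5):
    runs = []
    for _ in range(2):
        state = _fresh_state(ints5)
        rng = np.random.Generator(np.random.Philox(key=[9, 1]))
        state = mcci_augment(state, 40, rng)
        runs.append((state.alphas.copy(), state.betas.copy()))
    np.testing.assert_array_equal(runs[0][0], runs[1][0])
    np.testing.assert_array_equal(runs[0][1], runs[1][1])


def test_augment_adds_allowed_substitutions():
    ints = make_fixture("random-hermitian", 8, M=5, n_elec=4,
                        orbsym=[0, 1, 0, 1, 2])
    state = _fresh_state(ints, target=0)
    rng = np.random.Generator(np.random.Philox(key=[3, 1]))
    state = mcci_augment(state, 60, rng)
    ref = Determinant(int(state.alphas[0]), int(state.betas[0]))
    for a, b in zip(state.alphas[1:], state.betas[1:]):
        d = Determinant(int(a), int(b))
        assert 1 <= excitation_degree(ref, d) <= 2
        assert (string_irrep(d.alpha, ints.orbsym)
                ^ string_irrep(d.beta, ints.orbsym)) == 0
        assert d.alpha.bit_count() == 2 and d.beta.bit_count() == 2


def test_augment_saturated_space():
    ints = make_fixture("random-hermitian", 4, M=2, n_elec=2)
    state = _fresh_state(ints)
    rng = np.random.Generator(np.random.Philox(key=[1, 1]))
    # saturate: the full space of (2 orb, 1a1b) has 4 determinants
    for it in range(1, 8):
        state = mcci_augment(state, 50,
                             np.random.Generator(np.random.Philox(key=[1, it])))
    n = len(state)
    assert n == 4
    state2 = mcci_augment(state, 50, rng)
    assert len(state2) == 4  # nothing left to add


def test_hsub_incremental_vs_rebuild(ints5, rng):
    state = _fresh_state(ints5)
    for it in range(1, 6):
        gen = np.random.Generator(np.random.Philox(key=[17, it]))
        state = mcci_augment(state, 25, gen)
        if it % 2 == 0 and len(state) > 3:
            state.diagonalize()
            drop = [int(x) for x in
                    gen.choice(np.arange(1, len(state)), 2, replace=False)]
            keep = np.setdiff1d(np.arange(len(state)), drop)
            state.alphas = state.alphas[keep]
            state.betas = state.betas[keep]
            state.new_flags = state.new_flags[keep]
            state.coeffs = None
            state = subspace_hamiltonian_update(state, added=[],
                                                removed=drop)
        rebuilt = _kernels.h_dense(state.alphas, state.betas,
                                   state.ints.h, state.ints.eri)
        np.testing.assert_allclose(state.H_sub, rebuilt, atol=1e-12)


def test_hsub_add_then_remove_restores(ints5):
    state = _fresh_state(ints5)
    gen = np.random.Generator(np.random.Philox(key=[23, 1]))
    state = mcci_augment(state, 20, gen)
    H0 = state.H_sub.copy()
    n0 = len(state)
    state = mcci_augment(state, 20,
                         np.random.Generator(np.random.Philox(key=[23, 2])))
    drop = list(range(n0, len(state)))
    state.alphas = state.alphas[:n0]
    state.betas = state.betas[:n0]
    state.new_flags = state.new_flags[:n0]
    state = subspace_hamiltonian_update(state, added=[], removed=drop)
    np.testing.assert_allclose(state.H_sub, H0, atol=0)


def test_hsub_empty_update_is_noop(ints5):
    state = _fresh_state(ints5)
    H0 = state.H_sub.copy()
    state = subspace_hamiltonian_update(state, added=[], removed=[])
    np.testing.assert_array_equal(state.H_sub, H0)


def test_hsub_unknown_removal(ints5):
    state = _fresh_state(ints5)
    with pytest.raises(ValueError, match="unknown"):
        subspace_hamiltonian_update(state, added=[], removed=[5])


def test_prune_zero_cutoff_removes_nothing(ints5):
    state = _fresh_state(ints5, c_min=0.0)
    state = mcci_augment(state, 30,
                         np.random.Generator(np.random.Philox(key=[2, 1])))
    state.diagonalize()
    n = len(state)
    state = mcci_prune(state, full=True)
    assert len(state) == n


def test_prune_unit_cutoff_keeps_reference(ints5):
    state = _fresh_state(ints5, c_min=1.0)
    state = mcci_augment(state, 30,
                         np.random.Generator(np.random.Philox(key=[2, 1])))
    state.diagonalize()
    state = mcci_prune(state, full=True)
    kept = {(int(a), int(b)) for a, b in zip(state.alphas, state.betas)}
    ref = reference_determinant(ints5)
    assert (ref.alpha, ref.beta) in kept
    # anything else kept must genuinely have |c| >= 1
    assert len(state) <= 2


def test_prune_invariant(ints5):
    state = _fresh_state(ints5, c_min=0.05)
    for it in range(1, 4):
        state = mcci_augment(state, 40,
                             np.random.Generator(np.random.Philox(key=[5, it])))
    state.diagonalize()
    state = mcci_prune(state, full=True)
    state.diagonalize()
    cmax = np.max(np.abs(state.coeffs), axis=1)
    # after a full prune every non-reference config passed the cutoff when
    # pruned; the reference is index 0 and always protected
    assert len(state) >= 1


def test_mcci_zero_cutoff_reaches_fci(ints5, e_fci5):
    wfn, history, state = mcci_run(
        ints5, c_min=0.0, seed=3,
        opts=MCCIOptions(max_iter=80, conv_threshold=1e-9))
    assert history[-1][2][0] == pytest.approx(e_fci5, abs=1e-8)


def test_mcci_reproducible(ints5):
    h1 = mcci_run(ints5, c_min=1e-3, seed=42,
                  opts=MCCIOptions(max_iter=40))[1]
    h2 = mcci_run(ints5, c_min=1e-3, seed=42,
                  opts=MCCIOptions(max_iter=40))[1]
    assert len(h1) == len(h2)
    for (i1, n1, e1), (i2, n2, e2) in zip(h1, h2):
        assert (i1, n1) == (i2, n2)
        np.testing.assert_array_equal(e1, e2)


def test_mcci_variational(ints5, e_fci5):
    _, history, _ = mcci_run(ints5, c_min=5e-3, seed=1,
                             opts=MCCIOptions(max_iter=40))
    for _, _, e in history:
        assert e[0] >= e_fci5 - 1e-10
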