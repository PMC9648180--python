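import numpy as np
import pytest

from cirdm.determinants import Determinant, ExcitationInfo, excitation_info
from cirdm.fci import CIVector, fci_solve
from cirdm.integrals import PHYSICISTS, SpinFreeIntegrals, convert_notation
from cirdm.rdm import (RDM2, energy_from_rdms, rdm1_direct, rdm1_from_rdm2,
                       rdm2_from_fci, rdm2_from_sd_list, rdm2_naive,
                       rdm2_update_no_diff, rdm2_update_one_diff,
                       rdm2_update_two_diff, read_rdm2_text, write_rdm2_text)
from cirdm.stringspace import enumerate_strings
from cirdm.wavefunction import WavefunctionSD
from conftest import random_wavefunction
from secondq import FockOracle

ORACLE_M = 3


@pytest.fixture(scope="module")
def oracle():
    return FockOracle(ORACLE_M)


def _oracle_rdm2(orc, wfn):
    vec = orc.vector(((d.alpha, d.beta), c) for d, c in wfn)
    return orc.rdm2(vec)


def test_single_closed_shell_two_electrons():
    wfn = WavefunctionSD.from_dict(2, {(0b01, 0b01): 1.0})
    G = rdm2_naive(wfn, 2).gamma
    expected = np.zeros((2,) * 4)
    expected[0, 0, 0, 0] = 2.0
    np.testing.assert_allclose(G, expected, atol=1e-14)


def test_single_open_shell_pair_vs_oracle(oracle):
    wfn = WavefunctionSD.from_dict(ORACLE_M, {(0b011, 0): 1.0})
    G = rdm2_naive(wfn, 2).gamma[:2, :2, :2, :2]
    ref = _oracle_rdm2(oracle, wfn)[:2, :2, :2, :2]
    np.testing.assert_allclose(G, ref, atol=1e-14)
    # same-spin pair: Coulomb +1 on prrp, exchange -1 on prpr
    assert G[0, 1, 1, 0] == 1.0 and G[1, 0, 0, 1] == 1.0
    assert G[0, 1, 0, 1] == -1.0 and G[1, 0, 1, 0] == -1.0


@pytest.mark.parametrize("na,nb,ndet", [(1, 1, 5), (2, 1, 7), (2, 2, 9),
                                        (3, 2, 9)])
@pytest.mark.parametrize("strategy", [1, 2, 3])
def test_naive_strategies_vs_operator_oracle(oracle, rng, na, nb, ndet,
                                             strategy):
    wfn = random_wavefunction(ORACLE_M, na, nb, ndet, rng)
    ref = _oracle_rdm2(oracle, wfn)
    got = rdm2_naive(wfn, strategy).gamma
    np.testing.assert_allclose(got, ref, atol=1e-12)


def test_search_builder_vs_oracle(oracle, rng):
    wfn = random_wavefunction(ORACLE_M, 2, 2, 9, rng)
    np.testing.assert_allclose(rdm2_from_sd_list(wfn).gamma,
                               _oracle_rdm2(oracle, wfn), atol=1e-12)


def test_strategies_agree_on_larger_system(rng):
    wfn = random_wavefunction(6, 2, 2, 40, rng)
    g1 = rdm2_naive(wfn, 1).gamma
    g2 = rdm2_naive(wfn, 2).gamma
    g3 = rdm2_naive(wfn, 3).gamma
    g4 = rdm2_from_sd_list(wfn).gamma
    for g in (g2, g3, g4):
        np.testing.assert_allclose(g, g1, atol=1e-12)


def test_update_two_diff_mixed_spin_fires_two_cases():
    # alpha 0->1, beta 0->2 from |0a 0b> to |1a 2b>
    info = excitation_info(Determinant(0b010, 0b100), Determinant(0b001, 0b001))
    G = np.zeros((3,) * 4)
    rdm2_update_two_diff(G, 0.5, 0.5, info)
    assert np.count_nonzero(G) == 2  # only the spin-matched pairings fire
    assert G[1, 2, 0, 0] != 0.0 and G[2, 1, 0, 0] != 0.0


def test_update_two_diff_same_spin_fires_four_cases():
    info = excitation_info(Determinant(0b1100, 0), Determinant(0b0011, 0))
    G = np.zeros((4,) * 4)
    rdm2_update_two_diff(G, 1.0, 1.0, info)
    assert np.count_nonzero(G) == 4
    vals = sorted(G[G != 0.0])
    assert vals[0] == -vals[-1]


def test_update_two_diff_wrong_degree():
    info = excitation_info(Determinant(0b01, 0b01), Determinant(0b10, 0b01))
    with pytest.raises(ValueError):
        rdm2_update_two_diff(np.zeros((2,) * 4), 1.0, 1.0, info)


def test_update_one_diff_vs_oracle(oracle, rng):
    # two-determinant expansion differing by one spin orbital
    data = {(0b011, 0b001): 0.8, (0b101, 0b001): 0.6}
    wfn = WavefunctionSD.from_dict(3, data)
    np.testing.assert_allclose(rdm2_naive(wfn, 2).gamma,
                               _oracle_rdm2(oracle, wfn), atol=1e-13)


def test_update_one_diff_wrong_degree():
    info = ExcitationInfo(2, (0, 1), (2, 3), (), (), 1)
    with pytest.raises(ValueError):
        rdm2_update_one_diff(np.zeros((4,) * 4), 1.0, 1.0, info, [])


def test_update_no_diff_one_electron():
    G = np.zeros((3,) * 4)
    rdm2_update_no_diff(G, 1.0, Determinant(0b001, 0))
    assert np.count_nonzero(G) == 0


def test_trace_single_determinant():
    wfn = WavefunctionSD.from_dict(4, {(0b0011, 0b0011): 1.0})
    g2 = rdm2_naive(wfn, 2)
    assert abs(g2.trace() - 4 * 3) < 1e-12
    g2.validate()


def test_trace_random(rng):
    wfn = random_wavefunction(5, 2, 2, 30, rng)
    g2 = rdm2_naive(wfn, 2)
    assert abs(g2.trace() - 4 * 3) < 1e-9


def test_hermiticity_group(rng):
    wfn = random_wavefunction(4, 2, 2, 20, rng)
    G = rdm2_naive(wfn, 2).gamma
    np.testing.assert_allclose(G, G.transpose(1, 0, 3, 2), atol=1e-12)
    np.testing.assert_allclose(G, G.transpose(3, 2, 1, 0), atol=1e-12)


def test_rdm1_direct_examples(oracle, rng):
    wfn = WavefunctionSD.from_dict(3, {(0b011, 0b011): 1.0})
    g = rdm1_direct(wfn).gamma
    np.testing.assert_allclose(g, np.diag([2.0, 2.0, 0.0]), atol=1e-14)
    wfn = random_wavefunction(3, 2, 1, 8, rng)
    vec = oracle.vector(((d.alpha, d.beta), c) for d, c in wfn)
    np.testing.assert_allclose(rdm1_direct(wfn).gamma, oracle.rdm1(vec),
                               atol=1e-12)
    g1 = rdm1_direct(wfn)
    np.testing.assert_allclose(g1.gamma, g1.gamma.T, atol=1e-12)


def test_contraction_matches_direct(rng):
    wfn = random_wavefunction(5, 2, 2, 25, rng)
    g_direct = rdm1_direct(wfn).gamma
    g_contracted = rdm1_from_rdm2(rdm2_naive(wfn, 2)).gamma
    np.testing.assert_allclose(g_contracted, g_direct, atol=1e-10)
    assert abs(np.trace(g_contracted) - 4.0) < 1e-9


def test_rdm1_from_rdm2_requires_two_electrons():
    with pytest.raises(ValueError):
        rdm1_from_rdm2(RDM2(np.zeros((2,) * 4), 2, 1), n_elec=1)


def test_energy_identity_on_toy_fci(toy_ints6):
    res = fci_solve(toy_ints6, n_roots=1, tol=1e-11)
    E, vec = res[0]
    g2 = rdm2_from_fci(vec)
    g1 = rdm1_from_rdm2(g2)
    ints_p = convert_notation(toy_ints6, PHYSICISTS)
    assert abs(energy_from_rdms(ints_p, g1, g2) - E) < 1e-9


def test_energy_closed_shell_determinant(toy_ints):
    wfn = WavefunctionSD.from_dict(4, {(0b0011, 0b0011): 1.0})
    g2 = rdm2_naive(wfn, 2)
    g1 = rdm1_from_rdm2(g2)
    ints_p = convert_notation(toy_ints, PHYSICISTS)
    h, eri = ints_p.h, ints_p.eri
    # restricted single-determinant energy expression
    occ = [0, 1]
    e_ref = ints_p.e_core + sum(2 * h[i, i] for i in occ)
    for i in occ:
        for j in occ:
            e_ref += 2 * eri[i, j, i, j] - eri[i, j, j, i]
    assert abs(energy_from_rdms(ints_p, g1, g2) - e_ref) < 1e-10


def test_energy_zero_integrals():
    ints = SpinFreeIntegrals(M=2, n_elec=2, ms2=0, e_core=0.77,
                             h=np.zeros((2, 2)), eri=np.zeros((2,) * 4),
                             notation=PHYSICISTS)
    wfn = WavefunctionSD.from_dict(2, {(1, 1): 1.0})
    g2 = rdm2_naive(wfn, 2)
    assert energy_from_rdms(ints, rdm1_from_rdm2(g2), g2) == 0.77


def test_energy_convention_mismatch(toy_ints6):
    ints_p = convert_notation(toy_ints6, PHYSICISTS)
    g2 = RDM2(np.zeros((6,) * 4), 6, 4, convention="halved")
    with pytest.raises(ValueError, match="convention"):
        energy_from_rdms(ints_p, rdm1_from_rdm2(RDM2(np.zeros((6,) * 4), 6, 4)),
                         g2)


def test_fci_structured_equals_naive(toy_ints):
    res = fci_solve(toy_ints, n_roots=1, tol=1e-11)
    _, vec = res[0]
    g_struct = rdm2_from_fci(vec)
    wfn = vec.as_wavefunction().normalized()
    g_naive = rdm2_naive(wfn, 2)
    np.testing.assert_allclose(g_struct.gamma, g_naive.gamma, atol=1e-10)


def test_sd_list_equals_fci_structured_on_full_list(toy_ints):
    _, vec = fci_solve(toy_ints, n_roots=1, tol=1e-11)[0]
    wfn = vec.as_wavefunction().normalized()
    np.testing.assert_allclose(rdm2_from_sd_list(wfn).gamma,
                               rdm2_from_fci(vec).gamma, atol=1e-10)


def test_sd_list_mcci_like(rng, toy_ints6):
    wfn = random_wavefunction(6, 2, 2, 50, rng)
    np.testing.assert_allclose(rdm2_from_sd_list(wfn).gamma,
                               rdm2_naive(wfn, 2).gamma, atol=1e-12)


def test_isolated_determinants_contribute_diagonal_only():
    # two determinants separated by more than a double substitution
    data = {(0b000011, 0b000011): 0.8, (0b110000, 0b110000): -0.6}
    wfn = WavefunctionSD.from_dict(6, data)
    G = rdm2_from_sd_list(wfn).gamma
    ref = np.zeros((6,) * 4)
    rdm2_update_no_diff(ref, 0.64, Determinant(0b000011, 0b000011))
    rdm2_update_no_diff(ref, 0.36, Determinant(0b110000, 0b110000))
    np.testing.assert_allclose(G, ref, atol=1e-14)


def test_pair_visit_scaling(rng):
    """Linked-pair walk grows like N_SD * M^2 for fixed electron count."""
    ratios = []
    sizes = []
    for M in (6, 8, 10, 12):
        sa = enumerate_strings(M, 1)
        C = rng.standard_normal((len(sa), len(sa)))
        C /= np.linalg.norm(C)
        vec = CIVector(sa, sa, C, 0, None)
        g2 = rdm2_from_fci(vec)
        n_sd = len(sa) ** 2
        ratios.append(g2.pair_visits / n_sd)
        sizes.append(M)
    slope = np.polyfit(np.log(sizes), np.log(ratios), 1)[0]
    assert abs(slope - 2.0) < 0.2  # within 10 percent of quadratic


def test_text_dump_round_trip(tmp_path, rng):
    wfn = random_wavefunction(4, 2, 1, 10, rng)
    g2 = rdm2_naive(wfn, 2)
    write_rdm2_text(g2, tmp_path / "g.txt")
    back = read_rdm2_text(tmp_path / "g.txt")
    np.testing.assert_allclose(back.gamma, g2.gamma, atol=1e-14)
    assert back.n_elec == g2.n_elec and back.convention == g2.convention


def test_unnormalized_input_rejected():
    wfn = WavefunctionSD.from_dict(2, {(1, 1): 2.0})
    with pytest.raises(ValueError, match="norm"):
        rdm2_naive(wfn, 2)
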