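import numpy as np
import pytest

from cirdm import _kernels
from cirdm.fixtures import make_fixture
from cirdm.integrals import (CHEMISTS, PHYSICISTS, FcidumpFormatError,
                             SpinFreeIntegrals, convert_notation,
                             fold_frozen_core, read_fcidump, write_fcidump)
from conftest import all_determinants

# pyscf direct_spin1 on the identical deterministic fixture (external oracle)
PYSCF_FCI_SEED42 = -7.459402060717


def test_minimal_parse(tmp_path):
    p = tmp_path / "min.fcidump"
    p.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n  ORBSYM=1,1,\n  ISYM=1,\n"
                 "&END\n0.5 1 1 1 1\n")
    ints = read_fcidump(p)
    assert ints.M == 2 and ints.n_elec == 2
    assert ints.eri[0, 0, 0, 0] == 0.5
    # all 8 permutations filled (trivially identical indices here)
    assert ints.h[0, 0] == 0.0 and ints.e_core == 0.0


def test_permutations_filled(tmp_path):
    p = tmp_path / "perm.fcidump"
    p.write_text("&FCI NORB=3,NELEC=2,MS2=0,\n&END\n0.25 1 2 3 3\n")
    ints = read_fcidump(p)
    for idx in [(0, 1, 2, 2), (1, 0, 2, 2), (2, 2, 0, 1), (2, 2, 1, 0)]:
        assert ints.eri[idx] == 0.25


def test_round_trip(tmp_path, toy_ints):
    p = tmp_path / "rt.fcidump"
    write_fcidump(toy_ints, p)
    back = read_fcidump(p)
    assert back.M == toy_ints.M
    assert back.n_elec == toy_ints.n_elec
    assert back.ms2 == toy_ints.ms2
    assert abs(back.e_core - toy_ints.e_core) < 1e-12
    np.testing.assert_allclose(back.h, toy_ints.h, atol=1e-12)
    np.testing.assert_allclose(back.eri, toy_ints.eri, atol=1e-12)
    np.testing.assert_array_equal(back.orbsym, toy_ints.orbsym)


def test_zero_hamiltonian_write(tmp_path):
    ints = SpinFreeIntegrals(M=2, n_elec=2, ms2=0, e_core=1.25,
                             h=np.zeros((2, 2)), eri=np.zeros((2,) * 4))
    p = tmp_path / "zero.fcidump"
    write_fcidump(ints, p)
    lines = [ln for ln in p.read_text().splitlines() if ln.strip()]
    assert lines[-1].split()[1:] == ["0", "0", "0", "0"]
    assert len(lines) == 5  # 4 header lines + E_core record


def test_single_line_per_symmetry_class(tmp_path):
    eri = np.zeros((3,) * 4)
    val = 0.7
    for (p, q) in [(0, 1), (1, 0)]:
        for (r, s) in [(1, 2), (2, 1)]:
            eri[p, q, r, s] = val
            eri[r, s, p, q] = val
    ints = SpinFreeIntegrals(M=3, n_elec=2, ms2=0, e_core=0.0,
                             h=np.zeros((3, 3)), eri=eri)
    ints.validate()
    p = tmp_path / "uniq.fcidump"
    write_fcidump(ints, p)
    lines = p.read_text().splitlines()
    data = lines[lines.index("&END") + 1:]
    eri_lines = [ln for ln in data if ln.split()[3] != "0"]
    assert len(eri_lines) == 1


def test_errors(tmp_path):
    with pytest.raises(FcidumpFormatError, match="NORB"):
        p = tmp_path / "a"
        p.write_text("&FCI NELEC=2,\n&END\n")
        read_fcidump(p)
    with pytest.raises(FcidumpFormatError, match="outside"):
        p = tmp_path / "b"
        p.write_text("&FCI NORB=2,NELEC=2,\n&END\n1.0 3 1 1 1\n")
        read_fcidump(p)
    with pytest.raises(FcidumpFormatError, match=r":4"):
        p = tmp_path / "c"
        p.write_text("&FCI NORB=2,NELEC=2,\n&END\n1.0 1 2 1 2\n"
                     "2.0 2 1 2 1\n")
        read_fcidump(p)


def test_write_requires_chemists(tmp_path, toy_ints):
    phys = convert_notation(toy_ints, PHYSICISTS)
    with pytest.raises(ValueError, match="chemists"):
        write_fcidump(phys, tmp_path / "x")


def test_convert_notation_hand_example():
    eri = np.zeros((2,) * 4)
    for idx in [(0, 1, 0, 1), (1, 0, 0, 1), (0, 1, 1, 0), (1, 0, 1, 0)]:
        eri[idx] = 0.3
    ints = SpinFreeIntegrals(M=2, n_elec=2, ms2=0, e_core=0.0,
                             h=np.zeros((2, 2)), eri=eri)
    phys = convert_notation(ints, PHYSICISTS)
    # chemists (01|01) becomes physicists <00|11>
    assert phys.eri[0, 0, 1, 1] == 0.3


def test_convert_involution(toy_ints):
    twice = convert_notation(convert_notation(toy_ints, PHYSICISTS), CHEMISTS)
    np.testing.assert_array_equal(twice.eri, toy_ints.eri)
    assert twice.notation == CHEMISTS


def test_converted_table_symmetry(toy_ints):
    phys = convert_notation(toy_ints, PHYSICISTS)
    phys.validate()
    np.testing.assert_allclose(phys.eri, phys.eri.transpose(1, 0, 3, 2),
                               atol=1e-12)


def test_fold_empty_is_identity(toy_ints):
    out = fold_frozen_core(toy_ints, [])
    np.testing.assert_array_equal(out.h, toy_ints.h)
    assert out.e_core == toy_ints.e_core


def test_fold_all_occupied_gives_determinant_energy(toy_ints):
    # freeze the closed-shell determinant: E_core equals its diagonal energy
    phys = convert_notation(toy_ints, PHYSICISTS)
    folded = fold_frozen_core(toy_ints, [0, 1])
    det_bits = 0b0011
    e_det = _kernels.sc_element(det_bits, det_bits, det_bits, det_bits,
                                phys.h, phys.eri) + toy_ints.e_core
    assert abs(folded.e_core - e_det) < 1e-12
    assert folded.n_elec == 0 and folded.M == 2


def test_fold_matches_restricted_diagonalization():
    ints = make_fixture("random-hermitian", 3, M=3, n_elec=4)
    folded = fold_frozen_core(ints, [0])
    phys = convert_notation(ints, PHYSICISTS)
    # dense FCI restricted to determinants with orbital 0 doubly occupied
    dets = [d for d in all_determinants(3, 2, 2)
            if d.alpha & 1 and d.beta & 1]
    H = np.array([[_kernels.sc_element(d1.alpha, d1.beta, d2.alpha, d2.beta,
                                       phys.h, phys.eri)
                   for d2 in dets] for d1 in dets])
    e_restricted = np.linalg.eigvalsh(H)[0] + ints.e_core
    fphys = convert_notation(folded, PHYSICISTS)
    dets2 = all_determinants(2, 1, 1)
    H2 = np.array([[_kernels.sc_element(d1.alpha, d1.beta, d2.alpha, d2.beta,
                                        fphys.h, fphys.eri)
                    for d2 in dets2] for d1 in dets2])
    e_folded = np.linalg.eigvalsh(H2)[0] + folded.e_core
    assert abs(e_folded - e_restricted) < 1e-10


def test_fold_commutes_with_convert(toy_ints):
    a = fold_frozen_core(convert_notation(toy_ints, PHYSICISTS), [0])
    b = convert_notation(fold_frozen_core(toy_ints, [0]), PHYSICISTS)
    np.testing.assert_allclose(a.eri, b.eri, atol=1e-12)
    np.testing.assert_allclose(a.h, b.h, atol=1e-12)
    assert abs(a.e_core - b.e_core) < 1e-12


def test_fold_overlap_error(toy_ints):
    with pytest.raises(ValueError):
        fold_frozen_core(toy_ints, [9])


def test_h2_like_dense_oracle(tmp_path):
    ints = make_fixture("two-orbital-pair", 0, path=tmp_path / "h2.fcidump")
    back = read_fcidump(tmp_path / "h2.fcidump")
    phys = convert_notation(back, PHYSICISTS)
    dets = all_determinants(2, 1, 1)
    H = np.array([[_kernels.sc_element(d1.alpha, d1.beta, d2.alpha, d2.beta,
                                       phys.h, phys.eri)
                   for d2 in dets] for d1 in dets])
    e_dense = np.linalg.eigvalsh(H)[0]
    from cirdm.fci import fci_solve
    e_fci = fci_solve(back, n_roots=1, tol=1e-11)[0][0]
    assert abs(e_dense + back.e_core - e_fci) < 1e-10


def test_fci_matches_external_oracle(toy_ints):
    """Independent established FCI (pyscf, frozen value) on the same dump."""
    from cirdm.fci import fci_solve
    e = fci_solve(toy_ints, n_roots=1, tol=1e-11)[0][0]
    assert abs(e - PYSCF_FCI_SEED42) < 1e-8


def test_validate_rejects_bad_symmetry(toy_ints):
    bad = toy_ints.copy()
    bad.eri[0, 1, 2, 3] += 1.0
    with pytest.raises(ValueError, match="symmetry"):
        bad.validate()
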