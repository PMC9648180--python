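"""Regenerate the packaged reference FCIDUMP files.

Requires pyscf (not a runtime dependency of the package itself).  The
molecule/basis setups match the benchmark systems used by the test and
acceptance suites:

* Ne  / 6-31G* with 6 Cartesian d components (15 orbitals), RHF, D2h
* CO  / 6-31G at r = 2.1316 a0 (18 orbitals), RHF, C2v
* CO  / 6-31G at r = 4.0 a0 (stretched), RHF, C2v
* CO  / cc-pVDZ with Cartesian d (30 orbitals), RHF, C2v
* O2  / 6-31G at r = 1.2075 Angstrom, ROHF triplet (Ms=1), D2h

ORBSYM is written in the MOLPRO convention (1-based codes whose
zero-based values multiply by XOR for D2h and its subgroups).
All orbitals are kept; frozen-core folding is done by the consumer.

Usage:  python scripts/make_reference_fcidumps.py [outdir]
"""

import sys

import numpy as np
from pyscf import gto, scf, ao2mo, symm

# MOLPRO irrep code tables (1-based).  code-1 is XOR-multiplicative.
MOLPRO_CODES = {
    "D2h": {"Ag": 1, "B3u": 2, "B2u": 3, "B1g": 4, "B1u": 5, "B2g": 6, "B3g": 7, "Au": 8},
    "C2v": {"A1": 1, "B1": 2, "B2": 3, "A2": 4},
}


def write_fcidump(path, h, eri_s8, ecore, norb, nelec, ms2, orbsym, isym=1, tol=1e-12):
    idx = np.tril_indices(norb)
    pair_of = {}
    n = 0
    for p, q in zip(*idx):
        pair_of[n] = (p, q)
        n += 1
    with open(path, "w") as f:
        f.write(f"&FCI NORB={norb},NELEC={nelec},MS2={ms2},\n")
        f.write("  ORBSYM=" + ",".join(str(s) for s in orbsym) + ",\n")
        f.write(f"  ISYM={isym},\n")
        f.write("&END\n")
        npair = norb * (norb + 1) // 2
        for ij in range(npair):
            i, j = pair_of[ij]
            for kl in range(ij + 1):
                k, l = pair_of[kl]
                v = eri_s8[ij * (ij + 1) // 2 + kl]
                if abs(v) > tol:
                    f.write(f"{v:23.16e} {i+1:3d} {j+1:3d} {k+1:3d} {l+1:3d}\n")
        for i in range(norb):
            for j in range(i + 1):
                if abs(h[i, j]) > tol:
                    f.write(f"{h[i, j]:23.16e} {i+1:3d} {j+1:3d}   0   0\n")
        f.write(f"{ecore:23.16e}   0   0   0   0\n")


def dump(mol, mf, group, path):
    mo = mf.mo_coeff
    norb = mo.shape[1]
    hcore = mf.get_hcore()
    h = mo.T @ hcore @ mo
    eri_s8 = ao2mo.restore(8, ao2mo.full(mol, mo), norb)
    labels = symm.label_orb_symm(mol, mol.irrep_name, mol.symm_orb, mo)
    orbsym = [MOLPRO_CODES[group][str(x)] for x in labels]
    nelec = mol.nelectron
    ms2 = mol.spin
    write_fcidump(path, h, eri_s8, mol.energy_nuc(), norb, nelec, ms2, orbsym)
    print(f"{path}: norb={norb} nelec={nelec} ms2={ms2} E_scf={mf.e_tot:.10f}")
    print("  orbsym:", orbsym)
    print("  occ   :", mf.mo_occ.astype(int).tolist())


def main(outdir):
    # Ne / 6-31G* Cartesian d
    mol = gto.M(atom="Ne 0 0 0", basis="6-31g*", cart=True, symmetry="D2h")
    mf = scf.RHF(mol).run(conv_tol=1e-12)
    dump(mol, mf, "D2h", f"{outdir}/ne_631gstar.fcidump")

    # CO / 6-31G equilibrium (2.1316 a0)
    mol = gto.M(atom=f"C 0 0 0; O 0 0 {2.1316}", unit="Bohr",
                basis="6-31g", symmetry="C2v")
    mf = scf.RHF(mol).run(conv_tol=1e-12)
    dump(mol, mf, "C2v", f"{outdir}/co_631g_eq.fcidump")

    # CO / 6-31G stretched (4 a0)
    mol = gto.M(atom="C 0 0 0; O 0 0 4.0", unit="Bohr",
                basis="6-31g", symmetry="C2v")
    mf = scf.RHF(mol).run(conv_tol=1e-12)
    mf = scf.RHF(mol).newton().run(mf.make_rdm1())
    dump(mol, mf, "C2v", f"{outdir}/co_631g_stretched.fcidump")

    # CO / cc-pVDZ Cartesian d, equilibrium
    mol = gto.M(atom="C 0 0 0; O 0 0 2.1316", unit="Bohr",
                basis="cc-pvdz", cart=True, symmetry="C2v")
    mf = scf.RHF(mol).run(conv_tol=1e-12)
    dump(mol, mf, "C2v", f"{outdir}/co_ccpvdz.fcidump")

    # O2 / 6-31G triplet, 1.2075 Angstrom
    mol = gto.M(atom="O 0 0 0; O 0 0 1.2075", basis="6-31g",
                spin=2, symmetry="D2h")
    mf = scf.ROHF(mol).run(conv_tol=1e-12)
    dump(mol, mf, "D2h", f"{outdir}/o2_631g.fcidump")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else "src/cirdm/data")
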