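"""Optional in-process integral provider backed by pyscf.

The package itself never computes Gaussian integrals or SCF orbitals; for
named molecule/basis setups this adapter asks pyscf (if installed) for the
molecular-orbital integrals and returns them under the same
:class:`~cirdm.integrals.SpinFreeIntegrals` contract as ``read_fcidump``.
"""

from __future__ import annotations

import numpy as np

from .integrals import MOLPRO_IRREP_NAMES, SpinFreeIntegrals

__all__ = ["molecule_integrals"]


def molecule_integrals(atom: str, basis: str, charge: int = 0, spin: int = 0,
                       symmetry: str = None, cart: bool = False,
                       unit: str = "Angstrom") -> SpinFreeIntegrals:
    """RHF/ROHF molecular-orbital integrals for a named setup.

    ``cart=True`` selects Cartesian d functions (6 components).  Raises a
    RuntimeError naming the missing dependency when pyscf is unavailable.
    """
    try:
        from pyscf import ao2mo, gto, scf, symm
    except ImportError as exc:
        raise RuntimeError(
            "the named-molecule provider requires pyscf, which is not "
            "installed; supply an FCIDUMP file instead") from exc

    mol = gto.M(atom=atom, basis=basis, charge=charge, spin=spin,
                symmetry=symmetry or False, cart=cart, unit=unit)
    mf = scf.RHF(mol) if spin == 0 else scf.ROHF(mol)
    mf.conv_tol = 1e-12
    mf.run()
    if not mf.converged:
        raise RuntimeError("SCF did not converge for the requested setup")
    mo = mf.mo_coeff
    norb = mo.shape[1]
    h = mo.T @ mf.get_hcore() @ mo
    from pyscf.ao2mo import restore
    eri = restore(1, ao2mo.full(mol, mo), norb)

    if symmetry:
        labels = symm.label_orb_symm(mol, mol.irrep_name, mol.symm_orb, mo)
        names = MOLPRO_IRREP_NAMES[symmetry]
        orbsym = np.array([names.index(str(x)) for x in labels],
                          dtype=np.int64)
        group = symmetry
    else:
        orbsym = np.zeros(norb, dtype=np.int64)
        group = "C1"
    return SpinFreeIntegrals(M=norb, n_elec=mol.nelectron, ms2=mol.spin,
                             e_core=float(mol.energy_nuc()), h=h, eri=eri,
                             notation="chemists", orbsym=orbsym,
                             point_group=group)
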