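# cirdm

String-based configuration interaction and spin-free two-electron reduced
density matrices (2-RDMs) in Python.

The package implements, on top of an FCIDUMP integral interface:

* **Bitwise Slater–Condon machinery** — alpha/beta orbital strings as
  integer bitsets, excitation degree/holes/particles/signs via popcount
  and lowest-set-bit operations (`cirdm.determinants`, numba-accelerated
  kernels in `cirdm._kernels`).
* **String-driven FCI** — per-channel excitation tables, symmetry-blocked
  sigma builds (`H b` without forming `H`), block Davidson with thick
  restarts and an Olsen-corrected diagonal preconditioner, and
  histogram-based determinant-space counting that handles
  billion-determinant spaces instantly (`cirdm.stringspace`, `cirdm.fci`).
* **Spin-free 2-RDM construction** (`cirdm.rdm`) with four equivalent
  strategies: orbital-then-spin all-pairs, bitwise all-pairs, bitwise
  `i <= j` with hermitization, and the fast FCI-structured walk that
  visits only single/double-linked pairs (O(N_SD M²)); plus the
  search-based builder for general selected-CI expansions.  The 2-RDM is
  stored without the energy formula's factor of ½, so
  `E = Σ h γ + ½ Σ ⟨pr|qs⟩ Γ + E_core` and `Tr Γ = N(N−1)`.
* **Selected CI** — an MCCI-style loop (random configuration
  augmentation, stored subspace Hamiltonian with incremental updates,
  Davidson warm starts, coefficient-cutoff pruning with periodic full
  prunes) and truncated CI(n) solvers (`cirdm.selected`).
* **Spin projection** — exact S² application via ladder operators and
  Löwdin projection of configuration state functions onto Slater
  determinant expansions (`cirdm.spin`).
* **Metrics** — the multireference character `Σ cᵢ²(1−cᵢ²)` and
  unnormalized root-sum-square error measures with global-phase
  alignment (`cirdm.metrics`).

Benchmark FCIDUMP files (Ne/6-31G*, CO/6-31G at equilibrium and 4 a0,
CO/cc-pVDZ, triplet O2/6-31G) are packaged under `cirdm/data/`; they were
generated with RHF/ROHF orbitals and can be regenerated with
`scripts/make_reference_fcidumps.py` (requires pyscf, which is otherwise
optional and only used by the `named-molecule` provider adapter).

## CLI

All functionality is exposed through one entry point:

```bash
cirdm count --system ne-631gs --irrep Ag            # 125861 determinants
cirdm count --system co-631g-stretched --irrep A1 --level 6
cirdm fci --system ne-631gs --irrep Ag --roots 2 --out ne.state
cirdm ci --fcidump toy.fcidump --level 2
cirdm mcci --fcidump toy.fcidump --cmin 5e-4 --seed 7 --out mcci.state
cirdm rdm --state mcci.state --fcidump toy.fcidump --out gamma.txt
cirdm metrics --ref fci.state --test mcci.state --fcidump toy.fcidump \
      --what energy,rdm2,wavefunction
cirdm project-csf --occ 0,1u,2u --k 1 --ms2 0
cirdm make-fixture --kind random-hermitian --seed 1 --out toy.fcidump
```

States are stored as plain-text `(bitstring, bitstring, coefficient)`
tables and 2-RDMs as sparse `p r s q value` dumps; `--summary` writes a
machine-readable JSON record of any run.

FCIDUMP `ORBSYM` codes follow the MOLPRO convention (for D2h and its
subgroups `code − 1` multiplies by bitwise XOR, which is the encoding used
internally).

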