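"""Registry of the packaged benchmark FCIDUMP files.

Each file holds all molecular orbitals of its setup; frozen-core folding is
applied at load time so the folding code path is exercised everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .integrals import MOLPRO_IRREP_NAMES, fold_frozen_core, read_fcidump

__all__ = ["SYSTEMS", "data_path", "load_system", "irrep_code"]


@dataclass(frozen=True)
class BenchmarkSystem:
    filename: str
    point_group: str
    frozen: tuple
    ground_irrep: str
    description: str


SYSTEMS = {
    "ne-631gs": BenchmarkSystem(
        "ne_631gstar.fcidump", "D2h", (0,), "Ag",
        "Ne, 6-31G* with 6 Cartesian d components (15 orbitals), RHF"),
    "co-631g-eq": BenchmarkSystem(
        "co_631g_eq.fcidump", "C2v", (0, 1), "A1",
        "CO, 6-31G at r = 2.1316 a0 (18 orbitals), RHF"),
    "co-631g-stretched": BenchmarkSystem(
        "co_631g_stretched.fcidump", "C2v", (0, 1), "A1",
        "CO, 6-31G at r = 4 a0 (18 orbitals), RHF"),
    "co-ccpvdz": BenchmarkSystem(
        "co_ccpvdz.fcidump", "C2v", (0, 1), "A1",
        "CO, cc-pVDZ with Cartesian d (30 orbitals) at r = 2.1316 a0, RHF"),
    "o2-631g": BenchmarkSystem(
        "o2_631g.fcidump", "D2h", (0, 1), "B1g",
        "O2 triplet (Ms=1), 6-31G at r = 1.2075 Angstrom (18 orbitals), ROHF"),
}


def data_path(name: str):
    sys = SYSTEMS[name]
    return resources.files("cirdm").joinpath("data", sys.filename)


def irrep_code(point_group: str, name: str) -> int:
    """XOR-encoded irrep code (MOLPRO position - 1) from an irrep label."""
    return MOLPRO_IRREP_NAMES[point_group].index(name)


def load_system(name: str, fold: bool = True):
    """Read a packaged FCIDUMP; returns (integrals, target_irrep_code)."""
    sys = SYSTEMS[name]
    with resources.as_file(data_path(name)) as p:
        ints = read_fcidump(p, point_group=sys.point_group)
    if fold and sys.frozen:
        ints = fold_frozen_core(ints, sys.frozen)
    return ints, irrep_code(sys.point_group, sys.ground_irrep)
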