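import sys
from itertools import combinations
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cirdm.determinants import Determinant  # noqa: E402
from cirdm.fixtures import make_fixture  # noqa: E402
from cirdm.wavefunction import WavefunctionSD  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_ints():
    """Deterministic random 8-fold-symmetric 4-orbital, 4-electron system."""
    return make_fixture("random-hermitian", 42, M=4, n_elec=4)


@pytest.fixture(scope="session")
def toy_ints6():
    return make_fixture("random-hermitian", 7, M=6, n_elec=4)


def all_determinants(M, na, nb):
    def bits(c):
        v = 0
        for o in c:
            v |= 1 << o
        return v
    return [Determinant(bits(ca), bits(cb))
            for ca in combinations(range(M), na)
            for cb in combinations(range(M), nb)]


def random_wavefunction(M, na, nb, n_det, rng):
    dets = all_determinants(M, na, nb)
    idx = rng.choice(len(dets), size=min(n_det, len(dets)), replace=False)
    c = rng.standard_normal(len(idx))
    c /= np.linalg.norm(c)
    data = {(dets[i].alpha, dets[i].beta): ci for i, ci in zip(idx, c)}
    return WavefunctionSD.from_dict(M, data)


@pytest.fixture(scope="session")
def ne_system():
    """Ne/6-31G* integrals with the 1s orbital folded out."""
    from cirdm.datasets import load_system
    return load_system("ne-631gs")


@pytest.fixture(scope="session")
def ne_fci(ne_system):
    """Lowest two Ag (Ms=0) FCI roots of frozen-core Ne."""
    from cirdm.fci import fci_solve
    ints, target = ne_system
    return fci_solve(ints, target_irrep=target, n_roots=2, tol=1e-9)


def _co_state(name):
    from cirdm.datasets import load_system
    from cirdm.fci import fci_solve
    ints, target = load_system(name)
    return fci_solve(ints, target_irrep=target, n_roots=1, tol=2e-6,
                     guess_dim=600, max_subspace=24)[0]


_co_cache = {}


@pytest.fixture(scope="session")
def co_eq_fci():
    if "eq" not in _co_cache:
        _co_cache["eq"] = _co_state("co-631g-eq")
    return _co_cache["eq"]


@pytest.fixture(scope="session")
def co_stretched_fci():
    if "stretched" not in _co_cache:
        _co_cache["stretched"] = _co_state("co-631g-stretched")
    return _co_cache["stretched"]
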