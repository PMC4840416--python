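import numpy as np
import pytest

from miecsvm.energy import EnergyParams
from miecsvm.io import AtomRecord, ReceptorLigandComplex
from miecsvm.synthetic import SyntheticSpec, make_miec_dataset, make_toy_complex


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


@pytest.fixture(scope="session")
def toy_complex():
    """Small fully parameterized pocket: 6 residues x 3 atoms + 4-atom ligand
    (22 atoms total, within the brute-force oracle regime)."""
    spec = SyntheticSpec(
        n_residues=6, atoms_per_residue=3, n_ligand_atoms=4, k_informative=3, seed=11
    )
    return make_toy_complex(spec)


def _pair_complex(r=3.0, q_rec=0.3, q_lig=-0.4, radius=1.7, rmin_half=1.8, eps=0.1):
    a = AtomRecord(1, "A1", 0, "RES", "A", [0.0, 0.0, 0.0], q_rec, radius, rmin_half, eps)
    b = AtomRecord(
        2, "L1", 0, "LIG", "L", [r, 0.0, 0.0], q_lig, radius, rmin_half, eps
    )
    return ReceptorLigandComplex([a], [b], [(0, "RES")])


@pytest.fixture
def pair_complex_factory():
    return _pair_complex


@pytest.fixture(scope="session")
def miec_dataset():
    """Default study conditions: 25 inhibitors vs 500 background (1:20)."""
    return make_miec_dataset(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_miec_dataset():
    return make_miec_dataset(
        SyntheticSpec(n_inhibitors=12, n_noninhibitors=60, seed=5)
    )
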