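import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glp1qsar import (
    EnergyModelParams,
    ToyComplexSpec,
    gen_toy_complex,
    load_peptide_records,
    load_scan_pairs,
    read_structure,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def records():
    return load_peptide_records()

@pytest.fixture(scope="session")
def records_by_id(records):
    return {r.id: r for r in records}

@pytest.fixture(scope="session")
def scan_pairs():
    return load_scan_pairs()

@pytest.fixture(scope="session")
def params():
    return EnergyModelParams.default()

#: one planted interaction of each kind, at comfortable margins
FULL_SPEC = ToyComplexSpec(
    planted=(
        ("hbond", {"distance": 2.0, "angle": 180.0}),
        ("hydrophobic", {"distance": 4.0}),
        ("cation_pi", {"distance": 4.5, "angle": 0.0}),
        ("pi_pi", {"distance": 3.8, "angle": 0.0}),
        ("ion_ion", {"distance": 3.0}),
    ),
    decoy_atoms=8,
)

@pytest.fixture(scope="session")
def full_toy_pdb():
    return gen_toy_complex(FULL_SPEC)

@pytest.fixture(scope="session")
def full_toy_structure(full_toy_pdb):
    return read_structure(full_toy_pdb, "P")


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
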