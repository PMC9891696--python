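import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ximine import blosum62_scheme, simple_scheme

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def simple():
    return simple_scheme()


@pytest.fixture(scope="session")
def blosum():
    return blosum62_scheme()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(RESIDUES[i] for i in rng.integers(0, len(RESIDUES), size=length))
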