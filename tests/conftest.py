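import numpy as np
import pytest
from hypothesis import settings

from enacp.core import AMINO_ACIDS

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from enacp.seqio import PeptideRecord


def random_records(n, lmin=5, lmax=50, seed=0, prefix="r"):
    """Uniform-composition random peptides, deterministic per seed."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(lmin, lmax + 1))
        seq = "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, length))
        records.append(PeptideRecord(id=f"{prefix}{i}", sequence=seq))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def peptides_200():
    """The shared 200-peptide corpus used by oracle-equivalence checks."""
    return random_records(200, lmin=5, lmax=50, seed=4242)
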