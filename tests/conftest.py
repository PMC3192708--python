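import numpy as np
import pytest

from cytodiscord import Alignment, GroupMap


def aln(*seqs: str, ids=None) -> Alignment:
    """Build an alignment from raw sequence strings."""
    if ids is None:
        ids = tuple(f"s{i}" for i in range(len(seqs)))
    return Alignment(tuple(ids), tuple(s.upper() for s in seqs))


def random_aln(rng: np.random.Generator, n: int, L: int, alleles: int = 2) -> Alignment:
    """Random alignment with up to ``alleles`` bases per column."""
    bases = "AGCT"[:alleles]
    cols = rng.integers(0, alleles, size=(n, L))
    return aln(*("".join(bases[c] for c in row) for row in cols))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
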