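import numpy as np
import pytest

from seaati.ligand_io import LigandLibrary, LigandRead


def make_library(seqs, **kw):
    return LigandLibrary([LigandRead(f"r{i}", s) for i, s in enumerate(seqs)], **kw)


@pytest.fixture
def make_lib():
    return make_library


@pytest.fixture
def uniform_lib():
    """Factory for i.i.d. uniform ACGT libraries."""

    def _make(n=2000, length=30, seed=0, **kw):
        rng = np.random.default_rng(seed)
        base = np.frombuffer(b"ACGT", dtype=np.uint8)
        blob = base[rng.integers(0, 4, size=(n, length))].tobytes().decode()
        return make_library([blob[i * length : (i + 1) * length] for i in range(n)], **kw)

    return _make


@pytest.fixture
def random_joint():
    """Factory for random 64x64 joint count tables."""

    def _make(seed=0, total=5000):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(64 * 64) * 0.05)
        counts = rng.multinomial(total, probs).reshape(64, 64)
        from seaati.mutual_information import TrimerJoint

        return TrimerJoint(0, 3, counts, int(counts.sum()))

    return _make
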