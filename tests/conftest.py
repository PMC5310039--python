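import numpy as np
import pytest

from sigmapop.core_io import SequenceAlignment, Sense


@pytest.fixture
def make_alignment():
    def _make(seqs, ids=None, sense=Sense.MRNA):
        if ids is None:
            ids = [f"s{i}" for i in range(len(seqs))]
        return SequenceAlignment(tuple(ids), tuple(seqs), sense)

    return _make


@pytest.fixture
def random_alignment(make_alignment):
    """Random (non-coalescent) alignment factory for invariance checks."""

    def _make(n, L, seed=0, p_variant=0.1):
        rng = np.random.default_rng(seed)
        base = rng.integers(0, 4, size=L)
        codes = np.tile(base, (n, 1))
        mask = rng.random((n, L)) < p_variant
        codes[mask] = rng.integers(0, 4, size=int(mask.sum()))
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[row]) for row in codes]
        return make_alignment(seqs)

    return _make
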