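import numpy as np
import pytest

from introdiv.alignments import LocusAlignment, PopulationMap


@pytest.fixture
def popmap():
    return PopulationMap(
        assignments={
            "a1": "popA", "a2": "popA", "a3": "popA",
            "b1": "popB", "b2": "popB", "b3": "popB",
        },
        populations=("popA", "popB"),
    )


def make_alignment(seqs, pops=None, ids=None, name="locus"):
    """Build a LocusAlignment from a list of residue strings."""
    n = len(seqs)
    ids = ids or tuple(f"s{i}" for i in range(n))
    pops = pops or ("pop",) * n
    return LocusAlignment(
        locus_name=name, ids=tuple(ids), populations=tuple(pops), sequences=tuple(seqs)
    )


@pytest.fixture
def random_alignment_factory():
    def factory(n, L, n_pops=1, seed=0, alphabet="ACGT"):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]
        pops = tuple(f"pop{i % n_pops}" for i in range(n))
        return make_alignment(seqs, pops=pops)

    return factory
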