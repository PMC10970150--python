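import numpy as np
import pandas as pd
import pytest

import haplogeo as hg

BASES = np.array(list("ACGT"))


def make_sample_table(pop_sizes: dict, lon0: float = 100.0) -> pd.DataFrame:
    """Sample table for named populations laid out on a west-east line."""
    rows = []
    for k, (pop, n) in enumerate(pop_sizes.items()):
        for i in range(n):
            rows.append(
                (f"{pop}_{i:03d}", pop, lon0 + 2.0 * k, 25.0, 500.0 + 100.0 * k)
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "longitude", "latitude", "elevation"]
    )


def random_alignment(rng, n: int, L: int, locus: str = "locus", ids=None,
                     alphabet="ACGT", p=None):
    mat = rng.choice(list(alphabet), size=(n, L), p=p)
    seqs = ["".join(row) for row in mat]
    if ids is None:
        ids = [f"s{i:03d}" for i in range(n)]
    return hg.Alignment.from_sequences(locus, ids, seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def two_pop_fixed():
    """Two demes each fixed for a distinct haplotype (n=10 each)."""
    ids = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
    seqs = ["AAAAAAAAAA"] * 10 + ["TTTTTTTTTT"] * 10
    aln = hg.Alignment.from_sequences("toy", ids, seqs)
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "population": ["P1"] * 10 + ["P2"] * 10,
            "longitude": [100.0] * 10 + [110.0] * 10,
            "latitude": [25.0] * 20,
            "elevation": [500.0] * 20,
        }
    )
    return aln, samples
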