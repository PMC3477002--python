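import itertools
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_oracle importable

from taxosep import LabeledDataset, SequenceRecord


def random_pool(rng: np.random.Generator, max_records: int = 12,
                min_records: int = 4, seq_len=(30, 60)) -> LabeledDataset:
    """A small random labeled pool with tree-consistent lineages.

    Lineages are random paths through a small planted tree so that equal
    classes at a level imply equal classes above it (as with real
    taxonomies); sequences are uniform random ACGT.
    """
    branching = (2, 2, 1, 1, 1, 2, 2)
    prefixes = ("do", "ph", "cl", "or", "fa", "ge", "sp")
    m = int(rng.integers(min_records, max_records + 1))
    records = []
    for i in range(m):
        path = tuple(int(rng.integers(0, b)) for b in branching)
        lineage = tuple(
            prefixes[t] + ".".join(map(str, path[: t + 1])) for t in range(7)
        )
        L = int(rng.integers(seq_len[0], seq_len[1] + 1))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
        records.append(SequenceRecord(id=f"r{i:02d}", sequence=seq, lineage=lineage))
    return LabeledDataset(records, dataset_id="random")


def random_frequency_vector(rng: np.random.Generator, n: int = 2,
                            smoothed: bool = False):
    """A dense-support random frequency vector (Dirichlet) at word length n."""
    from taxosep import FrequencyVector

    dim = 4 ** n
    vals = rng.dirichlet(np.ones(dim))
    if smoothed:
        # emulate add-one smoothing of a pseudo-count draw: strictly positive
        vals = (vals * 50 + 1) / (50 + dim)
        vals = vals / vals.sum()
    return FrequencyVector(
        n=n, indices=np.arange(dim), values=vals, smoothed=smoothed, zero_value=0.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


def make_lineage(domain="doA", phylum="phA", klass="clA", order="orA",
                 family="faA", genus="geA", species="spA"):
    return (domain, phylum, klass, order, family, genus, species)
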