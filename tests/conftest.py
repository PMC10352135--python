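import numpy as np
import pandas as pd
import pytest

from tecre.intervals import ChromSizes, IntervalSet
from tecre.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle shared across tests (read-only)."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def chromsizes(bundle):
    return bundle.chromsizes


@pytest.fixture
def toy_chromsizes():
    return ChromSizes({"chr1": 10_000, "chr2": 8_000})


def random_intervalset(rng, n, chromsizes, max_len=400, named=False):
    """Random interval fixture on a toy genome (helper, not a fixture)."""
    chroms = list(chromsizes)
    rows = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chromsizes[chrom] - length + 1))
        name = f"f{i}" if named else "."
        rows.append((chrom, start, start + length, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return IntervalSet(df, chromsizes=chromsizes)
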