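import numpy as np
import pandas as pd
import pytest

from poolscan.io_formats import GenomeTable


@pytest.fixture
def simple_table():
    """Small two-chromosome table with a mix of coverages and counts."""
    rows = []
    rng = np.random.default_rng(7)
    pos = 0
    for chrom in ("chr1", "chr2"):
        pos = 0
        for _ in range(50):
            pos += int(rng.integers(50, 400))
            r1, r2 = rng.integers(10, 120, size=2)
            rows.append((chrom, pos, int(rng.integers(0, r1 + 1)), int(r1),
                         int(rng.integers(0, r2 + 1)), int(r2)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "k1", "r1", "k2", "r2"])
    return GenomeTable(df)


def make_table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "k1", "r1", "k2", "r2"])
    return GenomeTable(df)
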