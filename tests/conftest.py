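import numpy as np
import pytest

import rohscan as rs


@pytest.fixture
def toy_layout():
    """Two chromosomes, 10 kb spacing, 1 Mb + 0.5 Mb."""
    return rs.GenomeLayout(
        (("chr1", 1_000_000), ("chr2", 500_000)),
        {"chr1": np.arange(0, 1_000_000, 10_000),
         "chr2": np.arange(0, 500_000, 10_000)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_single_chrom(pos, chrom_len=None, name="chr1"):
    pos = np.asarray(pos, dtype=np.int64)
    if chrom_len is None:
        chrom_len = int(pos[-1]) + 1
    return rs.GenomeLayout(((name, chrom_len),), {name: pos})


def make_matrix(layout, rows, groups=None):
    rows = np.asarray(rows, dtype=np.int8)
    if rows.ndim == 1:
        rows = rows[None, :]
    samples = [(f"s{i}", (groups or ["g"] * len(rows))[i]) for i in range(len(rows))]
    return rs.GenotypeMatrix(layout=layout, samples=samples, calls=rows)
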